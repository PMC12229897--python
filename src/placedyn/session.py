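"""Session container and HDF5 persistence.

A :class:`SessionRecording` holds one mouse-day of a longitudinal
treadmill experiment: raw somatic fluorescence for every tracked cell,
the behavior streams sampled at the imaging frame rate, and the
lap/reward-condition structure (two cue-contingent reward locations,
RL1 and RL2, alternating in 12-18-lap blocks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SCHEMA_VERSION = "1"
CONDITIONS = ("RL1", "RL2")


class SchemaError(ValueError):
    """Raised when a session file is missing fields or inconsistent."""


@dataclass
class SessionRecording:
    """One mouse-day of imaging plus behavior.

    All per-frame arrays share the same length. ``lap_index`` maps each
    frame to the lap in progress at its timestamp (0-based); per-lap
    arrays (``lap_condition``, ``reward_cm``) have one entry per lap.
    """

    traces: np.ndarray            # (n_cells, n_frames) raw fluorescence
    position: np.ndarray          # (n_frames,) cm in [0, track_length)
    velocity: np.ndarray          # (n_frames,) cm/s
    licks: np.ndarray             # (n_frames,) bool
    lap_index: np.ndarray         # (n_frames,) int
    lap_condition: np.ndarray     # (n_laps,) str, RL1/RL2
    reward_cm: np.ndarray         # (n_laps,) reward location per lap
    frame_rate: float = 30.0
    track_length: float = 180.0
    mouse: str = "m0"
    day: int = 1
    attrs: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def n_laps(self) -> int:
        return len(self.lap_condition)

    def validate(self) -> None:
        n = self.n_frames
        for name in ("position", "velocity", "licks", "lap_index"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise SchemaError(
                    f"per-frame stream '{name}' has length {len(arr)}, expected {n}"
                )
        if len(self.reward_cm) != self.n_laps:
            raise SchemaError("reward_cm length does not match lap count")
        bad = set(np.unique(self.lap_condition)) - set(CONDITIONS)
        if bad:
            raise SchemaError(f"unknown condition labels: {sorted(bad)}")
        if self.n_laps and self.lap_index.max() >= self.n_laps:
            raise SchemaError("lap_index refers to laps beyond lap_condition")


_DATASETS = (
    "traces", "position", "velocity", "licks", "lap_index",
    "lap_condition", "reward_cm",
)


def write_session(session: SessionRecording, path) -> None:
    import h5py

    session.validate()
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["frame_rate_hz"] = session.frame_rate
        f.attrs["track_length_cm"] = session.track_length
        f.attrs["mouse"] = session.mouse
        f.attrs["day"] = session.day
        for k, v in session.attrs.items():
            f.attrs[k] = v
        f.create_dataset("traces", data=session.traces.astype(np.float32))
        f.create_dataset("position", data=session.position)
        f.create_dataset("velocity", data=session.velocity)
        f.create_dataset("licks", data=session.licks.astype(np.uint8))
        f.create_dataset("lap_index", data=session.lap_index.astype(np.int32))
        f.create_dataset(
            "lap_condition",
            data=np.asarray(session.lap_condition, dtype="S8"),
        )
        f.create_dataset("reward_cm", data=session.reward_cm)


def read_session(path) -> SessionRecording:
    import h5py

    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version is None:
            raise SchemaError("file has no schema_version attribute")
        if str(version) != SCHEMA_VERSION:
            raise SchemaError(f"unknown schema version {version!r}")
        missing = [name for name in _DATASETS if name not in f]
        if missing:
            raise SchemaError(f"missing dataset(s): {', '.join(missing)}")
        session = SessionRecording(
            traces=f["traces"][()],
            position=f["position"][()],
            velocity=f["velocity"][()],
            licks=f["licks"][()].astype(bool),
            lap_index=f["lap_index"][()],
            lap_condition=f["lap_condition"][()].astype("U8"),
            reward_cm=f["reward_cm"][()],
            frame_rate=float(f.attrs["frame_rate_hz"]),
            track_length=float(f.attrs["track_length_cm"]),
            mouse=str(f.attrs["mouse"]),
            day=int(f.attrs["day"]),
        )
    session.validate()
    return session


def import_nwb(path) -> SessionRecording:
    """Build a SessionRecording from a minimal NWB acquisition.

    Expects a fluorescence RoiResponseSeries and position/velocity/lick
    behavioral series. Requires the optional ``pynwb`` dependency.
    """
    try:
        import pynwb  # noqa: F401
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError(
            "NWB import requires the optional 'pynwb' package; "
            "install it or use the native HDF5 session format"
        ) from err
    raise NotImplementedError(
        "NWB import is an optional path; map your acquisition onto "
        "SessionRecording fields and use write_session instead"
    )
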