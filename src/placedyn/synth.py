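"""Synthetic multi-day experiments with known ground truth.

The generator emulates the study's recordings -- a tracked population
imaged for a week on a 180-cm treadmill with two cue-contingent reward
locations (RL1 at 100 cm, RL2 at 160 cm, cue at 40 cm) alternating in
12-18-lap blocks -- so every analysis stage can be tested against a
known answer. Place-field activity is injected with BTSP-like
structure: a large first (induction) event, subsequent laps whose
centre of mass drifts backward with a decaying per-lap offset, and a
field width set by the induction-lap running speed
(width = slope * v + intercept, defaults 0.80 and 18.95).

Cells divide into sustained and transient subpopulations with
configurable day-to-day survival; sustained cells keep their field
centre (small jitter) whenever they reappear. Baseline noise is white
at a configurable dF/F s.d. so the 3-s.d. transient threshold is
exercised. Velocity dips near the upcoming reward and licking
concentrates in the anticipatory zone, giving the behavioral metrics
something real to measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._track import circ_dist
from .session import SessionRecording
from .signal import compute_spatial_map

REWARD_CM = {"RL1": 100.0, "RL2": 160.0}
CUE_CM = 40.0
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class GeneratorConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Study-condition defaults for the synthetic experiment generator."""

    n_cells: int
    n_days: int = 7
    track_length: float = 180.0
    n_bins: int = 50
    frame_rate: float = 30.0
    laps_per_session: int = 126
    block_length_range: tuple = (12, 18)
    pc_fraction: float = 0.3            # day-1 PC probability per cell
    sustained_fraction: float = 0.22    # of PCs
    survival_sustained: float = 0.80    # per-day reappearance probability
    survival_transient: float = 0.22
    recruit_rate: float = 0.05          # daily recruitment of never-active cells
    context_selective_fraction: float = 0.5
    centre_jitter_cm: float = 4.0
    reliability: float = 0.85           # per-lap activity after onset
    field_amplitude: float = 0.8        # dF/F, ordinary post-onset laps
    induction_amplitude: float = 3.0    # dF/F, plateau-driven events
    btsp_width_slope: float = 0.80      # cm per (cm/s)
    btsp_width_intercept: float = 18.95
    drift_per_lap_cm: float = 1.0       # backward COM drift magnitude
    drift_decay_laps: float = 4.0
    noise_sd: float = 0.10              # dF/F
    plateau_rate: float = 0.06          # plateaus per lap
    salient_zones: tuple = ((91.0, 109.0), (151.0, 169.0))
    salience_bias: float = 0.3          # probability a PF centre lands in a zone
    base_velocity: float = 25.0         # cm/s
    velocity_lap_cv: float = 0.25       # lap-to-lap speed variability
    reward_dip: float = 0.5
    dip_width_cm: float = 12.0
    lick_rate_base: float = 0.005       # per frame
    lick_rate_anticipatory: float = 0.12
    f0: float = 100.0                   # raw-fluorescence baseline
    mouse: str = "m0"
    seed: int = 0

    def validate(self) -> None:
        probs = (
            self.pc_fraction, self.sustained_fraction, self.survival_sustained,
            self.survival_transient, self.recruit_rate,
            self.context_selective_fraction, self.reliability,
            self.salience_bias,
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise GeneratorConfigError("all probabilities must lie in [0, 1]")
        if self.laps_per_session < 1:
            raise GeneratorConfigError("laps_per_session must be >= 1")
        lo, hi = self.block_length_range
        if not 1 <= lo <= hi:
            raise GeneratorConfigError("invalid block_length_range")
        if self.n_cells < 0 or self.n_days < 1:
            raise GeneratorConfigError("n_cells must be >= 0 and n_days >= 1")

    @property
    def bin_width(self) -> float:
        return self.track_length / self.n_bins


@dataclass
class GroundTruth:
    """One row per active (cell, day, condition), plus the cell roster."""

    events: pd.DataFrame
    cells: pd.DataFrame

    def active_set(self) -> set:
        return set(
            zip(self.events["cell"], self.events["day"], self.events["condition"])
        )


def _session_rng(seed: int, mouse: str, day: int) -> np.random.Generator:
    import zlib

    mouse_tag = zlib.crc32(mouse.encode()) % (2**31)
    return np.random.default_rng([seed, mouse_tag, day])


def _generate_behavior(config: GeneratorConfig, rng: np.random.Generator):
    """Laps, condition blocks, position/velocity/lick streams for one day."""
    lo, hi = config.block_length_range
    conditions: list[str] = []
    current = "RL1" if rng.random() < 0.5 else "RL2"
    while len(conditions) < config.laps_per_session:
        block = int(rng.integers(lo, hi + 1))
        conditions.extend([current] * block)
        current = "RL2" if current == "RL1" else "RL1"
    lap_condition = np.array(conditions[: config.laps_per_session])
    reward_cm = np.array([REWARD_CM[c] for c in lap_condition])

    dt = 1.0 / config.frame_rate
    pos_chunks, vel_chunks, lap_chunks = [], [], []
    for lap, reward in enumerate(reward_cm):
        x = 0.0
        xs, vs = [], []
        lap_speed = config.base_velocity * max(
            1 + config.velocity_lap_cv * rng.standard_normal(), 0.4
        )
        while x < config.track_length:
            v = lap_speed * (
                1
                - config.reward_dip
                * np.exp(-circ_dist(x, reward, config.track_length) ** 2
                         / (2 * config.dip_width_cm**2))
            )
            v = max(v * (1 + 0.05 * rng.standard_normal()), 4.0)
            xs.append(x)
            vs.append(v)
            x += v * dt
        pos_chunks.append(np.array(xs))
        vel_chunks.append(np.array(vs))
        lap_chunks.append(np.full(len(xs), lap, dtype=np.int32))
    position = np.concatenate(pos_chunks)
    velocity = np.concatenate(vel_chunks)
    lap_index = np.concatenate(lap_chunks)

    n_ant_bins = 3
    bw = config.bin_width
    reward_per_frame = reward_cm[lap_index]
    ahead = np.mod(reward_per_frame - position, config.track_length)
    anticipatory = (ahead > 0) & (ahead <= n_ant_bins * bw)
    rate = np.where(anticipatory, config.lick_rate_anticipatory, config.lick_rate_base)
    licks = rng.random(position.size) < rate
    return position, velocity, licks, lap_index, lap_condition, reward_cm


def _draw_centre(config: GeneratorConfig, rng: np.random.Generator) -> float:
    if config.salient_zones and rng.random() < config.salience_bias:
        a, b = config.salient_zones[int(rng.integers(len(config.salient_zones)))]
        return float(rng.uniform(a, b))
    return float(rng.uniform(0, config.track_length))


def _plan_cells(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-cell plan: class, condition preference, base centre, active days."""
    rows = []
    for cell in range(config.n_cells):
        is_pc = rng.random() < config.pc_fraction
        sustained = rng.random() < config.sustained_fraction
        if rng.random() < config.context_selective_fraction:
            conds = ("RL1",) if rng.random() < 0.5 else ("RL2",)
        else:
            conds = ("RL1", "RL2")
        centre = _draw_centre(config, rng)
        survival = config.survival_sustained if sustained else config.survival_transient
        active_days: list[int] = []
        active = is_pc
        for day in range(1, config.n_days + 1):
            if day == 1:
                pass
            elif active_days and active_days[-1] == day - 1:
                active = rng.random() < survival
            elif not active_days:
                active = rng.random() < config.recruit_rate
                if active:
                    centre = _draw_centre(config, rng)
            else:
                active = False
            if active:
                active_days.append(day)
        rows.append(
            {
                "cell": cell,
                "class_label": "sustained" if sustained else "transient",
                "conditions": ",".join(conds),
                "base_centre_cm": centre,
                "active_days": ",".join(map(str, active_days)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cell", "class_label", "conditions", "base_centre_cm", "active_days"],
    )


def _gaussian_bump(position, centre, sigma, track_length):
    d = circ_dist(position, centre, track_length)
    return np.exp(-(d**2) / (2 * sigma**2))


def generate_experiment(config: GeneratorConfig):
    """Build one synthetic mouse: a SessionRecording per day + ground truth.

    Deterministic given ``config.seed``; the behavior and noise use one
    RNG stream per session derived from (seed, mouse, day), while the
    cell plan uses its own stream so per-session regeneration is stable.
    """
    config.validate()
    plan_rng = np.random.default_rng([config.seed, 7919])
    plan = _plan_cells(config, plan_rng)

    sessions: list[SessionRecording] = []
    truth_rows = []
    for day in range(1, config.n_days + 1):
        rng = _session_rng(config.seed, config.mouse, day)
        position, velocity, licks, lap_index, lap_condition, reward_cm = (
            _generate_behavior(config, rng)
        )
        n_frames = position.size
        # lap mean running speed on the binned grid (what the analysis reports)
        occupancy_map = compute_spatial_map(
            np.zeros((1, n_frames)), position, velocity, lap_index, lap_condition,
            n_bins=config.n_bins, track_length=config.track_length,
        )
        lap_velocity = occupancy_map.lap_velocity()

        dff = np.zeros((config.n_cells, n_frames), dtype=float)
        for _, cell_row in plan.iterrows():
            active_days = (
                set(map(int, cell_row["active_days"].split(",")))
                if cell_row["active_days"]
                else set()
            )
            if day not in active_days:
                continue
            cell = int(cell_row["cell"])
            for condition in cell_row["conditions"].split(","):
                cond_laps = np.flatnonzero(lap_condition == condition)
                if cond_laps.size < 6:
                    continue
                centre = float(cell_row["base_centre_cm"])
                if config.centre_jitter_cm > 0 and day > 1:
                    centre = float(
                        np.mod(
                            centre + plan_rng.normal(0, config.centre_jitter_cm),
                            config.track_length,
                        )
                    )
                onset_pos = int(plan_rng.integers(0, max(cond_laps.size // 3, 1)))
                onset_lap = int(cond_laps[onset_pos])
                v_ind = float(lap_velocity[onset_lap])
                width = config.btsp_width_slope * v_ind + config.btsp_width_intercept
                sigma = width / FWHM_TO_SIGMA

                post = cond_laps[onset_pos + 1 :]
                n_extra = max(config.plateau_rate * cond_laps.size - 1, 0.0)
                p_plateau = min(n_extra / max(post.size, 1), 1.0)
                n_active = 0
                for j, lap in enumerate(cond_laps[onset_pos:]):
                    induction = j == 0
                    if not induction and plan_rng.random() > config.reliability:
                        continue
                    n_active += 1
                    if induction:
                        amp = config.induction_amplitude
                        lap_centre = centre
                    else:
                        big = plan_rng.random() < p_plateau
                        amp = config.induction_amplitude if big else config.field_amplitude
                        amp *= 1 + 0.05 * plan_rng.standard_normal()
                        drift = -config.drift_per_lap_cm * np.sum(
                            np.exp(-np.arange(j) / config.drift_decay_laps)
                        )
                        lap_centre = np.mod(centre + drift, config.track_length)
                    frames = np.flatnonzero(lap_index == lap)
                    dff[cell, frames] += amp * _gaussian_bump(
                        position[frames], lap_centre, sigma, config.track_length
                    )
                truth_rows.append(
                    {
                        "mouse": config.mouse,
                        "day": day,
                        "condition": condition,
                        "cell": cell,
                        "centre_cm": centre,
                        "centre_bin": int(centre / config.bin_width) % config.n_bins,
                        "onset_lap": onset_lap,
                        "induction_velocity": v_ind,
                        "width_cm": width,
                        "class_label": cell_row["class_label"],
                        "n_active_laps": n_active,
                    }
                )
        if config.noise_sd > 0:
            dff += rng.normal(0, config.noise_sd, size=dff.shape)
        traces = config.f0 * (1.0 + dff)
        session = SessionRecording(
            traces=traces.astype(np.float32),
            position=position,
            velocity=velocity,
            licks=licks,
            lap_index=lap_index,
            lap_condition=lap_condition,
            reward_cm=reward_cm,
            frame_rate=config.frame_rate,
            track_length=config.track_length,
            mouse=config.mouse,
            day=day,
        )
        sessions.append(session)
    truth = GroundTruth(
        events=pd.DataFrame(
            truth_rows,
            columns=[
                "mouse", "day", "condition", "cell", "centre_cm", "centre_bin",
                "onset_lap", "induction_velocity", "width_cm", "class_label",
                "n_active_laps",
            ],
        ),
        cells=plan,
    )
    return sessions, truth


def inject_btsp_event(
    trace: np.ndarray,
    position: np.ndarray,
    lap_index: np.ndarray,
    lap: int,
    centre_cm: float,
    velocity_cmps: float,
    rng: np.random.Generator,
    amplitude: float = 3.0,
    post_amplitude: float = 1.2,
    n_post_laps: int = 5,
    width_slope: float = 0.80,
    width_intercept: float = 18.95,
    drift_per_lap_cm: float = 1.5,
    drift_decay_laps: float = 4.0,
    track_length: float = 180.0,
) -> tuple[np.ndarray, dict | None]:
    """Inject one BTSP-like induction into a dF/F trace.

    Adds a large event at ``centre_cm`` on ``lap`` plus ``n_post_laps``
    subsequent place-field laps with backward-drifting centres; the
    field width is ``width_slope * velocity + width_intercept``
    (the sustained-cell regression defaults). With ``amplitude`` 0 the
    trace is returned unchanged and no event is recorded.
    """
    if velocity_cmps <= 0:
        raise ValueError("induction velocity must be positive")
    n_laps = int(lap_index.max()) + 1 if lap_index.size else 0
    if not 0 <= lap < n_laps:
        raise IndexError(f"lap {lap} outside session of {n_laps} laps")
    if amplitude == 0:
        return trace, None
    out = np.asarray(trace, dtype=float).copy()
    width = width_slope * velocity_cmps + width_intercept
    sigma = width / FWHM_TO_SIGMA
    frames = np.flatnonzero(lap_index == lap)
    out[frames] += amplitude * _gaussian_bump(position[frames], centre_cm, sigma, track_length)
    for j in range(1, n_post_laps + 1):
        if lap + j >= n_laps:
            break
        drift = -drift_per_lap_cm * np.sum(np.exp(-np.arange(j) / drift_decay_laps))
        lap_centre = np.mod(centre_cm + drift, track_length)
        frames = np.flatnonzero(lap_index == lap + j)
        amp = post_amplitude * (1 + 0.05 * rng.standard_normal())
        out[frames] += amp * _gaussian_bump(position[frames], lap_centre, sigma, track_length)
    event = {
        "lap": lap,
        "amplitude": amplitude,
        "centre_cm": float(centre_cm),
        "induction_velocity": float(velocity_cmps),
        "width_cm": float(width),
    }
    return out, event


def synthesize_vm_trace(
    plateau_spec: list[tuple[float, float]],
    duration_s: float = 5.0,
    fs_hz: float = 20000.0,
    baseline_mv: float = -62.0,
    plateau_mv: float = -28.0,
    spike_rate_hz: float = 4.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Membrane-potential trace with spikes and specified plateaus.

    ``plateau_spec`` lists (onset_s, duration_ms) depolarizations that
    cross the -35-mV plateau threshold; overlapping entries raise.
    Spikes (dV/dt well above 25 V/s) ride on the trace at
    ``spike_rate_hz`` so the spike-removal step is exercised.
    """
    rng = np.random.default_rng() if rng is None else rng
    n = int(round(duration_s * fs_hz))
    vm = np.full(n, baseline_mv) + 0.3 * rng.standard_normal(n)

    ramp = int(round(2e-3 * fs_hz))  # edges slower than the spike dV/dt gate
    intervals = []
    for onset_s, dur_ms in plateau_spec:
        if dur_ms <= 0:
            raise ValueError("plateau durations must be positive")
        a = int(round(onset_s * fs_hz))
        b = a + int(round(dur_ms * fs_hz / 1000.0))
        if a - ramp < 0 or b + ramp > n:
            raise ValueError("plateau extends outside the trace")
        intervals.append((a, b))
    intervals.sort()
    for (a1, b1), (a2, b2) in zip(intervals, intervals[1:]):
        if a2 - ramp < b1 + ramp:
            raise ValueError("overlapping plateau specifications")
    for a, b in intervals:
        vm[a - ramp : a] = np.linspace(baseline_mv, plateau_mv, ramp, endpoint=False)
        vm[a:b] = plateau_mv + 0.3 * rng.standard_normal(b - a)
        vm[b : b + ramp] = np.linspace(plateau_mv, baseline_mv, ramp, endpoint=False)

    n_spikes = rng.poisson(spike_rate_hz * duration_s)
    rise = int(round(0.2e-3 * fs_hz))
    fall = int(round(1.0e-3 * fs_hz))
    for t in rng.uniform(0, duration_s, n_spikes):
        i = int(t * fs_hz)
        if i + rise + fall >= n:
            continue
        peak = 25.0
        vm[i : i + rise] += np.linspace(0, peak - vm[i], rise)
        vm[i + rise : i + rise + fall] += np.linspace(peak - vm[i], 0, fall)
    return vm
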