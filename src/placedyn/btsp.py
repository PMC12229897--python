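"""BTSP-event and plateau-potential detection.

Behavioral-timescale synaptic plasticity (BTSP) leaves a distinctive
fingerprint in calcium imaging: an abrupt, large first event followed
by a place field whose centre of mass sits *behind* the inducing event
(backward shift) and whose width grows with running speed at induction.
A putative BTSP event must satisfy four criteria:

1. a strong Ca2+ event -- amplitude in the top 20th percentile of the
   cell's events that session, and at least 1 dF/F;
2. only laps whose peak lies within 45 cm of the event peak count as
   PF-active for the remaining checks;
3. at least three of the five subsequent laps actively firing;
4. the average centre of mass (COM) of the post-firing laps is shifted
   backward (negative) relative to the event peak.

The minimum amplitude among a cell's detected BTSP events sets that
cell's session plateau threshold; events at or above it are counted as
putative dendritic plateau potentials.

Membrane-potential plateau detection (for intracellular recordings)
removes spikes around dV/dt threshold crossings, interpolates, and
merges -35-mV crossings separated by less than 150 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from ._track import bin_centres, circ_dist, circ_signed_diff, circ_weighted_mean

EVENT_PERCENTILE = 80.0
MIN_EVENT_AMP = 1.0
PEAK_GATE_CM = 45.0
POST_WINDOW = 5
POST_REQUIRED = 3

VM_PLATEAU_THRESHOLD_MV = -35.0
VM_MERGE_GAP_MS = 150.0
VM_LONG_MS = 150.0
SPIKE_DVDT_V_PER_S = 25.0
SPIKE_PRE_MS = 0.26
SPIKE_POST_MS = 3.0


@dataclass
class BtspEvent:
    cell: int
    day: int
    condition: str
    lap: int                   # session-level lap index of the event
    amplitude: float           # peak dF/F of the inducing event
    peak_location_cm: float
    com_shift_cm: float        # mean post-lap COM minus event peak (signed)
    induction_velocity: float  # mean running speed on the event lap, cm/s
    pf_width_cm: float         # FWHM of the post-event mean field
    is_first_of_session: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def lap_events(lap_bin_activity: np.ndarray) -> pd.DataFrame:
    """One Ca2+ event per lap: the lap's peak significant dF/F.

    Laps with no significant activity contribute no event. Peak ties
    break to the lowest bin index.
    """
    act = np.nan_to_num(np.atleast_2d(lap_bin_activity), nan=0.0)
    rows = []
    for lap in range(act.shape[0]):
        amp = act[lap].max()
        if amp > 0:
            rows.append({"lap": lap, "amplitude": amp, "peak_bin": int(np.argmax(act[lap]))})
    return pd.DataFrame(rows, columns=["lap", "amplitude", "peak_bin"])


def _field_width_fwhm(profile: np.ndarray, peak_bin: int, bin_width: float) -> float:
    """Full width at half maximum of a circular binned field profile.

    Half-max crossings are located by linear interpolation between bins,
    walking outward from the peak in both directions.
    """
    prof = np.nan_to_num(profile, nan=0.0)
    n = len(prof)
    peak = prof[peak_bin]
    if peak <= 0:
        return float("nan")
    half = peak / 2.0

    def walk(direction: int) -> float:
        dist = 0.0
        prev = peak
        for step in range(1, n):
            cur = prof[(peak_bin + direction * step) % n]
            if cur < half:
                frac = (prev - half) / (prev - cur) if prev != cur else 0.0
                return (step - 1 + frac) * bin_width
            prev = cur
            dist = step * bin_width
        return dist

    return walk(+1) + walk(-1)


def detect_btsp_events(
    lap_bin_activity: np.ndarray,
    lap_velocity: np.ndarray,
    bin_width: float = 3.6,
    track_length: float = 180.0,
    cell: int = 0,
    day: int = 1,
    condition: str = "RL1",
    percentile: float = EVENT_PERCENTILE,
    min_amplitude: float = MIN_EVENT_AMP,
) -> list[BtspEvent]:
    """Detect putative BTSP induction events in one cell's lap x bin map.

    ``lap_bin_activity`` holds the laps of a single reward condition in
    session order (rows); ``lap_velocity`` is the mean running speed per
    lap. Returns events satisfying all four criteria, each re-checkable
    from its fields.
    """
    act = np.nan_to_num(np.atleast_2d(lap_bin_activity), nan=0.0)
    n_laps, n_bins = act.shape
    if n_laps < POST_WINDOW + 1:
        return []
    events = lap_events(act)
    if events.empty:
        return []
    centres = bin_centres(n_bins, track_length)
    amp_threshold = max(np.percentile(events["amplitude"], percentile), min_amplitude)
    out: list[BtspEvent] = []
    for _, ev in events.iterrows():
        if ev["amplitude"] < amp_threshold:
            continue
        lap = int(ev["lap"])
        peak_cm = centres[int(ev["peak_bin"])]
        # criterion 2 gate applied to every other lap of the session
        lap_peaks = np.argmax(act, axis=1)
        firing = act.max(axis=1) > 0
        qualifies = firing & (circ_dist(centres[lap_peaks], peak_cm, track_length) <= PEAK_GATE_CM)
        # criterion 3: three of five subsequent laps actively firing
        window = qualifies[lap + 1 : lap + 1 + POST_WINDOW]
        if len(window) < POST_WINDOW or window.sum() < POST_REQUIRED:
            continue
        # criterion 4: mean COM of post-firing laps shifted backward
        post_laps = np.flatnonzero(qualifies)
        post_laps = post_laps[post_laps > lap]
        coms = []
        weights = []
        for pl in post_laps:
            near = circ_dist(centres, peak_cm, track_length) <= PEAK_GATE_CM
            w = act[pl] * near
            if w.sum() <= 0:
                continue
            coms.append(circ_weighted_mean(centres, w, track_length))
            weights.append(1.0)
        if not coms:
            continue
        shifts = circ_signed_diff(peak_cm, np.asarray(coms), track_length)
        com_shift = float(np.average(shifts, weights=weights))
        if com_shift >= 0:
            continue
        # width per post lap (each lap's own half-max span), then averaged;
        # measuring on the pooled mean would convolve in the backward drift
        widths = [
            _field_width_fwhm(act[pl], int(np.argmax(act[pl])), bin_width)
            for pl in post_laps
        ]
        width = float(np.nanmean(widths)) if widths else float("nan")
        out.append(
            BtspEvent(
                cell=cell,
                day=day,
                condition=condition,
                lap=lap,
                amplitude=float(ev["amplitude"]),
                peak_location_cm=float(peak_cm),
                com_shift_cm=com_shift,
                induction_velocity=float(lap_velocity[lap]),
                pf_width_cm=float(width),
            )
        )
    if out:
        out[0].is_first_of_session = True
    return out


def plateau_threshold_and_rate(
    btsp_events: list[BtspEvent],
    all_event_amplitudes: np.ndarray,
    n_laps: int,
) -> tuple[float, int, float]:
    """Plateau threshold, count and rate for one cell-session-condition.

    The threshold is the minimum amplitude among the cell's detected
    BTSP events; every Ca2+ event at or above it counts as a putative
    plateau. With no BTSP events the rate is undefined (NaN).
    """
    if not btsp_events:
        return float("nan"), 0, float("nan")
    threshold = min(ev.amplitude for ev in btsp_events)
    amps = np.asarray(all_event_amplitudes, dtype=float)
    count = int(np.sum(amps >= threshold))
    return float(threshold), count, count / n_laps


def pre_post_event_stats(
    event: BtspEvent,
    lap_bin_activity: np.ndarray,
    track_length: float = 180.0,
) -> dict:
    """Amplitude and reliability before vs after a first-of-session event.

    Mean lap-peak amplitude is taken over firing laps only; reliability
    is the fraction of laps that qualify as PF-active (criterion-2 gate
    around the event location). An event on the first lap leaves an
    empty pre-set (NaN amplitude, flagged).
    """
    act = np.nan_to_num(np.atleast_2d(lap_bin_activity), nan=0.0)
    n_laps, n_bins = act.shape
    centres = bin_centres(n_bins, track_length)
    lap_peaks = np.argmax(act, axis=1)
    firing = act.max(axis=1) > 0
    qualifies = firing & (
        circ_dist(centres[lap_peaks], event.peak_location_cm, track_length) <= PEAK_GATE_CM
    )
    amps = act.max(axis=1)
    pre = np.arange(n_laps) < event.lap
    post = np.arange(n_laps) > event.lap

    def side(mask):
        if mask.sum() == 0:
            return {"amplitude": float("nan"), "reliability": float("nan"), "n_laps": 0}
        fire = mask & qualifies
        amp = float(amps[fire].mean()) if fire.any() else 0.0
        return {
            "amplitude": amp,
            "reliability": float(qualifies[mask].mean()),
            "n_laps": int(mask.sum()),
        }

    return {"pre": side(pre), "post": side(post), "flagged_empty_pre": event.lap == 0}


def width_velocity_regression(events: list[BtspEvent]):
    """OLS of PF width (cm) on induction-lap velocity (cm/s).

    Returns (slope, intercept, p_value) for the velocity coefficient.
    """
    import statsmodels.api as sm

    if len(events) < 10:
        raise ValueError("need >= 10 events for the width-velocity regression")
    v = np.array([e.induction_velocity for e in events])
    w = np.array([e.pf_width_cm for e in events])
    keep = np.isfinite(v) & np.isfinite(w)
    v, w = v[keep], w[keep]
    if np.std(v) == 0:
        raise ValueError("degenerate velocity variance")
    model = sm.OLS(w, sm.add_constant(v)).fit()
    return float(model.params[1]), float(model.params[0]), float(model.pvalues[1])


@dataclass
class VmPlateau:
    onset_s: float
    duration_ms: float      # total time above threshold across merged crossings
    merged_from: int        # number of threshold crossings merged
    long_lasting: bool


def remove_spikes(vm_mv: np.ndarray, fs_hz: float) -> np.ndarray:
    """Delete and interpolate spikes from a membrane-potential trace.

    Spike onsets are upward crossings of dV/dt = 25 V/s; points 0.26 ms
    before to 3 ms after each onset are removed and the gap is linearly
    interpolated.
    """
    vm = np.asarray(vm_mv, dtype=float).copy()
    dvdt = np.gradient(vm) * fs_hz / 1000.0  # mV/sample -> V/s
    above = dvdt >= SPIKE_DVDT_V_PER_S
    onsets = np.flatnonzero(above & ~np.roll(above, 1))
    if onsets.size == 0:
        return vm
    pre = int(round(SPIKE_PRE_MS * fs_hz / 1000.0))
    post = int(round(SPIKE_POST_MS * fs_hz / 1000.0))
    cut = np.zeros(vm.size, dtype=bool)
    for idx in onsets:
        cut[max(idx - pre, 0) : min(idx + post + 1, vm.size)] = True
    keep = np.flatnonzero(~cut)
    if keep.size < 2:
        return vm
    vm[cut] = np.interp(np.flatnonzero(cut), keep, vm[keep])
    return vm


def detect_vm_plateaus(
    vm_mv: np.ndarray,
    fs_hz: float,
    threshold_mv: float = VM_PLATEAU_THRESHOLD_MV,
    merge_gap_ms: float = VM_MERGE_GAP_MS,
    long_ms: float = VM_LONG_MS,
    long_lasting_only: bool = True,
) -> list[VmPlateau]:
    """Detect plateau potentials in a membrane-potential trace.

    Spikes are removed and interpolated first. Threshold crossings of
    -35 mV define candidate plateaus; crossings separated by less than
    ``merge_gap_ms`` (consecutive theta cycles) merge into one event
    whose duration is the summed time above threshold. Events are
    long-lasting when that duration exceeds ``long_ms``.
    """
    if fs_hz < 10000:
        raise ValueError("sampling rate must be >= 10 kHz")
    vm = remove_spikes(vm_mv, fs_hz)
    above = vm >= threshold_mv
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    ms_per_sample = 1000.0 / fs_hz
    merged: list[list[int]] = [[starts[0], ends[0], ends[0] - starts[0], 1]]
    for s, e in zip(starts[1:], ends[1:]):
        gap_ms = (s - merged[-1][1]) * ms_per_sample
        if gap_ms < merge_gap_ms:
            merged[-1][1] = e
            merged[-1][2] += e - s
            merged[-1][3] += 1
        else:
            merged.append([s, e, e - s, 1])
    plateaus = [
        VmPlateau(
            onset_s=s / fs_hz,
            duration_ms=dur * ms_per_sample,
            merged_from=n,
            long_lasting=dur * ms_per_sample > long_ms,
        )
        for s, _, dur, n in merged
    ]
    if long_lasting_only:
        plateaus = [p for p in plateaus if p.long_lasting]
    return plateaus
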