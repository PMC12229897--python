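"""Place-field detection.

A cell has place-field (PF) activity in a behavioral epoch (one
12-18-lap block of a reward condition) when all four criteria hold:

1. the epoch's spatial information exceeds the 95th percentile of a
   shuffle null built by circularly rotating each lap's binned activity;
2. laps count as PF-active only when their peak dF/F falls within 54 cm
   (15 of 50 bins, circular) of the peak of the epoch-averaged activity;
3. an onset lap exists: the first instance where three of five laps
   show PF activity (sliding 5-lap window);
4. PF activity on the laps after the onset lap is reliable (>= 40%).

The PF location for a condition is the peak of the average lap activity
over all laps of the epochs that passed, reported at the bin centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from ._track import bin_centres, circ_dist

PEAK_GATE_CM = 54.0
RELIABILITY_THRESHOLD = 0.40
ONSET_WINDOW = 5
ONSET_REQUIRED = 3


@dataclass
class PlaceFieldRecord:
    cell: int
    day: int
    condition: str
    pf_location_cm: float
    onset_lap: int              # session-level lap index
    reliability: float
    spatial_info: float
    n_epochs_passed: int

    def to_dict(self) -> dict:
        return asdict(self)


def condition_epochs(lap_condition: np.ndarray) -> list[tuple[str, np.ndarray]]:
    """Split the session's lap sequence into contiguous condition blocks."""
    lap_condition = np.asarray(lap_condition)
    epochs: list[tuple[str, np.ndarray]] = []
    if lap_condition.size == 0:
        return epochs
    start = 0
    for i in range(1, len(lap_condition) + 1):
        if i == len(lap_condition) or lap_condition[i] != lap_condition[start]:
            epochs.append((str(lap_condition[start]), np.arange(start, i)))
            start = i
    return epochs


def spatial_information(epoch_map: np.ndarray, occupancy: np.ndarray) -> float:
    """Skaggs-style spatial information of the epoch's mean activity.

    Bits per unit mean activity: sum_i p_i (l_i / l_bar) log2(l_i / l_bar)
    with p_i the occupancy probability of bin i and l_i the mean activity
    there. Returns NaN for an all-missing epoch.
    """
    epoch_map = np.atleast_2d(epoch_map)
    occupancy = np.asarray(occupancy, dtype=float)
    occ = occupancy.sum(axis=0) if occupancy.ndim == 2 else occupancy
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rate = np.nanmean(epoch_map, axis=0)
    valid = np.isfinite(rate) & (occ > 0)
    if not valid.any():
        return float("nan")
    p = occ[valid] / occ[valid].sum()
    lam = rate[valid]
    lbar = float(np.sum(p * lam))
    if lbar <= 0:
        return 0.0
    ratio = lam / lbar
    terms = np.where(ratio > 0, p * ratio * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
    return float(terms.sum())


def shuffle_test(
    epoch_map: np.ndarray,
    occupancy: np.ndarray,
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, bool, float]:
    """95th-percentile shuffle test for spatial information.

    The null rotates each lap's binned activity circularly by an
    independent random offset. Returns (threshold, passed, observed).
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100 for a stable 95th percentile")
    rng = np.random.default_rng() if rng is None else rng
    epoch_map = np.atleast_2d(epoch_map)
    n_laps, n_bins = epoch_map.shape
    observed = spatial_information(epoch_map, occupancy)
    if not np.isfinite(observed):
        return float("nan"), False, observed
    null = np.empty(n_shuffles)
    cols = np.arange(n_bins)
    for s in range(n_shuffles):
        offsets = rng.integers(0, n_bins, size=n_laps)
        idx = np.mod(cols[None, :] - offsets[:, None], n_bins)
        shifted = np.take_along_axis(epoch_map, idx, axis=1)
        null[s] = spatial_information(shifted, occupancy)
    threshold = float(np.percentile(null, 95))
    return threshold, bool(observed > threshold), observed


def lap_activity_flags(
    epoch_map: np.ndarray,
    bin_width: float,
    track_length: float = 180.0,
    peak_gate_cm: float = PEAK_GATE_CM,
) -> tuple[np.ndarray, int]:
    """Which laps show PF activity, and the epoch-average peak bin.

    A lap is active iff it has significant activity (positive peak) and
    its peak lies within ``peak_gate_cm`` (circular) of the peak of the
    epoch-averaged activity. Peak ties break to the lowest bin index.
    """
    epoch_map = np.atleast_2d(epoch_map)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_rate = np.nanmean(epoch_map, axis=0)
    if not np.isfinite(mean_rate).any() or np.nanmax(mean_rate) <= 0:
        return np.zeros(epoch_map.shape[0], dtype=bool), -1
    peak_bin = int(np.nanargmax(mean_rate))
    centres = bin_centres(epoch_map.shape[1], track_length)
    active = np.zeros(epoch_map.shape[0], dtype=bool)
    filled = np.nan_to_num(epoch_map, nan=0.0)
    for lap in range(epoch_map.shape[0]):
        if filled[lap].max() <= 0:
            continue
        lap_peak = int(np.argmax(filled[lap]))
        active[lap] = (
            circ_dist(centres[peak_bin], centres[lap_peak], track_length) <= peak_gate_cm
        )
    return active, peak_bin


def find_onset_lap(active: np.ndarray) -> int | None:
    """First active lap of the earliest 5-lap window holding >= 3 active laps."""
    active = np.asarray(active, dtype=bool)
    n = len(active)
    for start in range(0, max(n - ONSET_WINDOW + 1, 1)):
        window = active[start : start + ONSET_WINDOW]
        if len(window) < ONSET_WINDOW:
            break
        if window.sum() >= ONSET_REQUIRED:
            first = start + int(np.argmax(window))
            return first
    return None


def detect_place_field(
    cell_map: np.ndarray,
    lap_condition: np.ndarray,
    occupancy: np.ndarray,
    condition: str,
    cell: int = 0,
    day: int = 1,
    bin_width: float = 3.6,
    track_length: float = 180.0,
    n_shuffles: int = 1000,
    reliability_threshold: float = RELIABILITY_THRESHOLD,
    rng: np.random.Generator | None = None,
) -> PlaceFieldRecord | None:
    """Apply the four PF criteria to one cell/condition; None if absent.

    Criterion 1 is evaluated per epoch; the cell-condition passes if any
    epoch passes all four criteria. Onset and reliability are taken from
    the earliest passing epoch; the reported location averages the laps
    of all passing epochs.
    """
    rng = np.random.default_rng() if rng is None else rng
    cell_map = np.atleast_2d(cell_map)
    passing: list[np.ndarray] = []
    onset_session: int | None = None
    reliability_out = float("nan")
    si_out = float("nan")
    for cond, laps in condition_epochs(lap_condition):
        if cond != condition:
            continue
        epoch = cell_map[laps]
        occ = occupancy[laps]
        threshold, passed_si, si = shuffle_test(epoch, occ, n_shuffles=n_shuffles, rng=rng)
        if not passed_si:
            continue
        active, _ = lap_activity_flags(epoch, bin_width, track_length)
        onset = find_onset_lap(active)
        if onset is None:
            continue
        after = active[onset + 1 :]
        if after.size == 0:
            continue
        reliability = float(after.mean())
        if reliability < reliability_threshold:
            continue
        passing.append(laps)
        if onset_session is None:
            onset_session = int(laps[onset])
            reliability_out = reliability
            si_out = si
    if not passing:
        return None
    all_laps = np.concatenate(passing)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_rate = np.nanmean(cell_map[all_laps], axis=0)
    peak_bin = int(np.nanargmax(np.nan_to_num(mean_rate, nan=-np.inf)))
    centres = bin_centres(cell_map.shape[1], track_length)
    return PlaceFieldRecord(
        cell=cell,
        day=day,
        condition=condition,
        pf_location_cm=float(centres[peak_bin]),
        onset_lap=onset_session,
        reliability=reliability_out,
        spatial_info=si_out,
        n_epochs_passed=len(passing),
    )


def detect_place_fields(
    spatial_map,
    day: int = 1,
    conditions: tuple[str, ...] = ("RL1", "RL2"),
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Run PF detection for every cell and condition of a session map.

    Returns the place_fields table: one row per detected (cell, day,
    condition) with location, onset lap, reliability and information.
    """
    rng = np.random.default_rng() if rng is None else rng
    records = []
    for cell in range(spatial_map.values.shape[0]):
        for condition in conditions:
            rec = detect_place_field(
                spatial_map.values[cell],
                spatial_map.lap_condition,
                spatial_map.occupancy,
                condition,
                cell=cell,
                day=day,
                bin_width=spatial_map.bin_width,
                track_length=spatial_map.track_length,
                n_shuffles=n_shuffles,
                rng=rng,
            )
            if rec is not None:
                records.append(rec.to_dict())
    columns = [
        "cell", "day", "condition", "pf_location_cm", "onset_lap",
        "reliability", "spatial_info", "n_epochs_passed",
    ]
    return pd.DataFrame.from_records(records, columns=columns)
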