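"""Fluorescence preprocessing and spatial activity maps.

Raw somatic fluorescence is converted to dF/F against a slow running
baseline (the median of a centred 25-s window), baseline noise is
estimated from the negative-going deviations around the histogram mode
of the dF/F distribution, and only significant transients (exceeding
3 s.d. of that noise) are retained as functional activity. Retained
activity is then averaged into lap x spatial-bin maps (50 bins of
3.6 cm on the 180-cm belt), using only frames where the animal ran
faster than 2 cm/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class SignalError(ValueError):
    """Raised for invalid fluorescence input (e.g. nonpositive baseline)."""


@dataclass
class DffTrace:
    values: np.ndarray    # dF/F per frame
    f0: np.ndarray        # running baseline per frame
    noise_sd: float | None = None


@dataclass
class SpatialActivityMap:
    """Per-cell lap x bin mean dF/F, with occupancy and running speed.

    ``values`` is (n_cells, n_laps, n_bins); bins the animal never
    visited above the speed threshold on a lap are NaN (missing), never
    zero -- zero would fake silence in unvisited bins.
    """

    values: np.ndarray          # (n_cells, n_laps, n_bins), NaN = missing
    occupancy: np.ndarray       # (n_laps, n_bins) qualifying frame counts
    velocity_map: np.ndarray    # (n_laps, n_bins) mean running speed, NaN = missing
    lap_condition: np.ndarray   # (n_laps,)
    bin_width: float
    track_length: float = 180.0

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]

    @property
    def n_laps(self) -> int:
        return self.values.shape[1]

    def lap_velocity(self) -> np.ndarray:
        """Mean running speed per lap over visited bins."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.velocity_map, axis=1)


def compute_dff(raw: np.ndarray, frame_rate: float, window_s: float = 25.0) -> DffTrace:
    """dF/F = (F - F0)/F0 with F0 the median of a centred moving window.

    The window is truncated at the trace edges rather than padded, so
    the first and last frames use only the available samples.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size < 1:
        raise SignalError("empty fluorescence series")
    if frame_rate <= 0:
        raise SignalError("frame_rate must be positive")
    window = max(1, int(round(window_s * frame_rate)))
    f0 = (
        pd.Series(raw)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    if np.any(f0 <= 0):
        raise SignalError("baseline F0 is nonpositive somewhere in the trace")
    return DffTrace(values=(raw - f0) / f0, f0=f0)


def estimate_baseline_noise(dff: DffTrace | np.ndarray) -> float:
    """Noise s.d. from deviations below the dF/F histogram mode.

    The mode is located with a coarse-to-fine histogram search; the s.d.
    is the root-mean-square of the negative-going deviations from the
    mode, which is insensitive to sparse positive transients.
    """
    values = dff.values if isinstance(dff, DffTrace) else np.asarray(dff, float)
    values = values[np.isfinite(values)]
    if values.size < 2 or np.ptp(values) == 0:
        warnings.warn("degenerate (constant) trace; noise s.d. set to 0")
        if isinstance(dff, DffTrace):
            dff.noise_sd = 0.0
        return 0.0
    mode = _histogram_mode(values)
    below = values[values <= mode]
    sd = float(np.sqrt(np.mean((below - mode) ** 2)))
    if isinstance(dff, DffTrace):
        dff.noise_sd = sd
    return sd


def _histogram_mode(values: np.ndarray) -> float:
    # Coarse pass over the full range, then refine around the peak with
    # bins ~1/10 of the coarse scale.
    lo, hi = values.min(), values.max()
    counts, edges = np.histogram(values, bins=100, range=(lo, hi))
    k = int(np.argmax(counts))
    coarse = 0.5 * (edges[k] + edges[k + 1])
    half = (edges[1] - edges[0]) * 1.5
    sel = values[(values >= coarse - half) & (values <= coarse + half)]
    if sel.size < 10:
        return float(coarse)
    counts, edges = np.histogram(sel, bins=30)
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


def detect_significant_transients(
    dff: DffTrace, n_sd: float = 3.0, noise_sd: float | None = None
) -> np.ndarray:
    """Boolean mask of frames inside transients exceeding ``n_sd`` x noise.

    Frames outside the mask carry no functional activity and are zeroed
    by :func:`functional_activity` before any spatial averaging.
    """
    if noise_sd is None:
        noise_sd = dff.noise_sd
    if noise_sd is None:
        noise_sd = estimate_baseline_noise(dff)
    return dff.values > n_sd * noise_sd


def functional_activity(dff: DffTrace, n_sd: float = 3.0) -> np.ndarray:
    """dF/F with sub-threshold frames zeroed."""
    mask = detect_significant_transients(dff, n_sd=n_sd)
    return np.where(mask, dff.values, 0.0)


def compute_spatial_map(
    activity: np.ndarray,
    position: np.ndarray,
    velocity: np.ndarray,
    lap_index: np.ndarray,
    lap_condition: np.ndarray,
    n_bins: int = 50,
    track_length: float = 180.0,
    speed_threshold: float = 2.0,
) -> SpatialActivityMap:
    """Average functional activity into lap x bin maps.

    ``activity`` is (n_cells, n_frames) masked dF/F (see
    :func:`functional_activity`). Only frames with velocity strictly
    above ``speed_threshold`` contribute; bins with no qualifying frames
    on a lap are NaN.
    """
    activity = np.atleast_2d(np.asarray(activity, dtype=float))
    n_cells, n_frames = activity.shape
    for name, arr in (("position", position), ("velocity", velocity), ("lap_index", lap_index)):
        if len(arr) != n_frames:
            raise SignalError(f"stream '{name}' is not aligned with traces")
    n_laps = len(lap_condition)
    bin_width = track_length / n_bins

    keep = np.asarray(velocity) > speed_threshold
    lap = np.asarray(lap_index)[keep]
    bins = np.clip(
        (np.mod(np.asarray(position)[keep], track_length) // bin_width).astype(int),
        0,
        n_bins - 1,
    )
    flat = lap * n_bins + bins
    counts = np.bincount(flat, minlength=n_laps * n_bins).reshape(n_laps, n_bins)

    vsum = np.bincount(flat, weights=np.asarray(velocity)[keep], minlength=n_laps * n_bins)
    with np.errstate(invalid="ignore"):
        vel_map = (vsum.reshape(n_laps, n_bins) / counts).astype(float)

    values = np.full((n_cells, n_laps, n_bins), np.nan)
    for c in range(n_cells):
        s = np.bincount(flat, weights=activity[c, keep], minlength=n_laps * n_bins)
        with np.errstate(invalid="ignore"):
            values[c] = s.reshape(n_laps, n_bins) / counts
    return SpatialActivityMap(
        values=values,
        occupancy=counts,
        velocity_map=vel_map,
        lap_condition=np.asarray(lap_condition),
        bin_width=bin_width,
        track_length=track_length,
    )
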