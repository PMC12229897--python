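"""Circular-track geometry helpers.

The belt is a 180-cm loop; all distances between track positions are
circular. The signed difference convention puts values in (-L/2, L/2],
with negative meaning *backward* relative to the running direction
(positions increase in the running direction).
"""

from __future__ import annotations

import numpy as np

DEFAULT_TRACK_LENGTH = 180.0


def circ_signed_diff(a, b, track_length: float = DEFAULT_TRACK_LENGTH):
    """Signed circular difference b - a, wrapped to (-L/2, L/2].

    Negative values are backward shifts (b behind a in running direction).
    """
    half = track_length / 2.0
    return half - np.mod(half - (np.asarray(b, dtype=float) - a), track_length)


def circ_dist(a, b, track_length: float = DEFAULT_TRACK_LENGTH):
    """Unsigned circular distance between track positions, in [0, L/2]."""
    return np.abs(circ_signed_diff(a, b, track_length))


def bin_centres(n_bins: int, track_length: float = DEFAULT_TRACK_LENGTH) -> np.ndarray:
    """Centre position (cm) of each spatial bin."""
    width = track_length / n_bins
    return (np.arange(n_bins) + 0.5) * width


def circ_weighted_mean(positions, weights, track_length: float = DEFAULT_TRACK_LENGTH) -> float:
    """Activity-weighted circular mean of track positions (cm)."""
    positions = np.asarray(positions, dtype=float)
    weights = np.asarray(weights, dtype=float)
    theta = positions * (2 * np.pi / track_length)
    s = np.sum(weights * np.sin(theta))
    c = np.sum(weights * np.cos(theta))
    if s == 0 and c == 0:
        return float("nan")
    ang = np.arctan2(s, c)
    return float(np.mod(ang, 2 * np.pi) * track_length / (2 * np.pi))
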