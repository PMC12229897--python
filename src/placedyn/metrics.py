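"""Discrimination, density, onset and behavioral metrics.

Trial-by-trial cosine similarity underlies the context-discrimination
indices: each lap's binned activity vector is l2-normalized and the lap
x lap similarity matrix is the outer product. The cellular (CDI) and
population (PDI) discrimination indices are the mean within-condition
minus between-condition similarity across rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SimilarityMatrix:
    values: np.ndarray        # (n_laps, n_laps)
    lap_labels: np.ndarray    # condition per lap
    row_norms: np.ndarray     # pre-normalization l2 norms


def similarity_matrix(maps, lap_labels) -> SimilarityMatrix:
    """Lap x lap cosine similarity.

    ``maps`` is a single cell's lap x bin activity (NaN treated as 0) or
    a sequence of such maps; multiple cells are horizontally
    concatenated into a fat matrix for the population version. Rows
    with zero norm yield zero similarity.
    """
    if isinstance(maps, (list, tuple)):
        mat = np.hstack([np.nan_to_num(np.atleast_2d(m), nan=0.0) for m in maps])
    else:
        mat = np.nan_to_num(np.atleast_2d(np.asarray(maps, dtype=float)), nan=0.0)
    if mat.shape[0] < 2:
        raise ValueError("need >= 2 laps for a similarity matrix")
    norms = np.linalg.norm(mat, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = mat / safe[:, None]
    c = unit @ unit.T
    c[norms == 0, :] = 0.0
    c[:, norms == 0] = 0.0
    return SimilarityMatrix(values=c, lap_labels=np.asarray(lap_labels), row_norms=norms)


def discrimination_index(sim: SimilarityMatrix) -> float:
    """Mean within-condition minus between-condition similarity (CDI/PDI).

    Per row: average similarity to same-condition laps minus average to
    the other condition, excluding the diagonal; rows (and columns) with
    zero activity are dropped rather than imputed. Averaged over rows,
    giving a value in [-1, 1].
    """
    labels = sim.lap_labels
    if len(np.unique(labels)) < 2:
        raise ValueError("both condition labels must be present")
    c = sim.values
    valid = sim.row_norms > 0
    diffs = []
    for i in np.flatnonzero(valid):
        same = valid & (labels == labels[i])
        same[i] = False
        other = valid & (labels != labels[i])
        if same.sum() < 1 or other.sum() < 1:
            continue
        diffs.append(c[i, same].mean() - c[i, other].mean())
    if not diffs:
        return float("nan")
    return float(np.mean(diffs))


def pf_density(
    locations_cm,
    track_length: float = 180.0,
    n_bins: int = 50,
    n_bootstrap: int = 10000,
    ci: float = 99.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """PF count per cm with a bootstrap CI of a uniform-random null.

    The null redraws the same number of locations uniformly on the
    track ``n_bootstrap`` times; bins whose observed density exceeds
    the upper CI bound are over-represented.
    """
    rng = np.random.default_rng() if rng is None else rng
    locations = np.asarray(locations_cm, dtype=float)
    if locations.size < 10:
        raise ValueError("need >= 10 PF locations for a density estimate")
    bin_width = track_length / n_bins
    edges = np.linspace(0, track_length, n_bins + 1)
    observed = np.histogram(locations, bins=edges)[0] / bin_width
    null = np.empty((n_bootstrap, n_bins))
    for b in range(n_bootstrap):
        draw = rng.uniform(0, track_length, size=locations.size)
        null[b] = np.histogram(draw, bins=edges)[0] / bin_width
    lo = np.percentile(null, (100 - ci) / 2, axis=0)
    hi = np.percentile(null, 100 - (100 - ci) / 2, axis=0)
    return pd.DataFrame(
        {
            "bin_start_cm": edges[:-1],
            "density_per_cm": observed,
            "ci_low": lo,
            "ci_high": hi,
            "over_represented": observed > hi,
        }
    )


def onset_lap_distributions(onsets_by_class: dict) -> dict:
    """Empirical onset-lap CDFs per class plus a two-sample KS test.

    ``onsets_by_class`` maps class label (e.g. 'sustained'/'transient')
    to arrays of onset laps. The KS statistic compares the two classes'
    distributions (two-sided asymptotic p).
    """
    classes = list(onsets_by_class)
    if len(classes) != 2:
        raise ValueError("expected exactly two classes")
    out = {"cdf": {}}
    for name in classes:
        x = np.sort(np.asarray(onsets_by_class[name], dtype=float))
        if x.size == 0:
            raise ValueError(f"class {name!r} is empty")
        out["cdf"][name] = (x, np.arange(1, x.size + 1) / x.size)
    ks = stats.ks_2samp(
        onsets_by_class[classes[0]], onsets_by_class[classes[1]], method="asymp"
    )
    out["ks_statistic"] = float(ks.statistic)
    out["p_value"] = float(ks.pvalue)
    return out


def day_to_day_correlation(maps_a, maps_b, common_cells=None) -> float:
    """Correlation of the population spatial representation across days.

    For each cell present on both days the condition-averaged spatial
    tuning vectors are concatenated over cells; the statistic is the
    Pearson correlation of the two population vectors. Returns NaN when
    fewer than 10 common cells are available.
    """
    if common_cells is None:
        common_cells = sorted(set(maps_a) & set(maps_b))
    if len(common_cells) < 10:
        return float("nan")
    va = np.concatenate([np.asarray(maps_a[c], dtype=float).ravel() for c in common_cells])
    vb = np.concatenate([np.asarray(maps_b[c], dtype=float).ravel() for c in common_cells])
    va = np.nan_to_num(va, nan=0.0)
    vb = np.nan_to_num(vb, nan=0.0)
    if np.std(va) == 0 or np.std(vb) == 0:
        return float("nan")
    return float(np.corrcoef(va, vb)[0, 1])


def lick_probability_map(
    licks: np.ndarray,
    position: np.ndarray,
    lap_index: np.ndarray,
    n_laps: int,
    n_bins: int = 50,
    track_length: float = 180.0,
) -> np.ndarray:
    """Laps x bins boolean table: lap had >= 1 lick inside the bin."""
    bin_width = track_length / n_bins
    table = np.zeros((n_laps, n_bins), dtype=bool)
    lick_frames = np.flatnonzero(licks)
    bins = np.clip(
        (np.mod(position[lick_frames], track_length) // bin_width).astype(int),
        0,
        n_bins - 1,
    )
    table[lap_index[lick_frames], bins] = True
    return table


def licking_selectivity(
    lick_table: np.ndarray,
    reward_bins: np.ndarray,
    cue_bin: int,
    n_anticipatory: int = 3,
    random_zone_bins: np.ndarray | None = None,
) -> float:
    """Selectivity of anticipatory licking for the reward location.

    P_lick(zone) is the fraction of laps with at least one lick inside
    the zone. The anticipatory zone is the ``n_anticipatory`` bins
    before each lap's reward bin; the random zone defaults to the three
    bins around the light-cue location, excluding any reward zone.
    selectivity = (P_ant - P_rand) / P_ant, NaN if P_ant = 0.
    """
    lick_table = np.asarray(lick_table, dtype=bool)
    n_laps, n_bins = lick_table.shape
    reward_bins = np.asarray(reward_bins, dtype=int)
    if len(reward_bins) != n_laps:
        raise ValueError("one reward bin per lap required")
    if random_zone_bins is None:
        candidates = np.mod(cue_bin + np.arange(-1, 2), n_bins)
        reward_zone = set()
        for rb in np.unique(reward_bins):
            for k in range(-n_anticipatory, 2):
                reward_zone.add(int(np.mod(rb + k, n_bins)))
        random_zone_bins = np.array(
            [b for b in candidates if b not in reward_zone], dtype=int
        )
        if random_zone_bins.size == 0:
            raise ValueError("random zone overlaps reward zones; pass bins explicitly")
    ant_hits = np.zeros(n_laps, dtype=bool)
    for lap in range(n_laps):
        zone = np.mod(reward_bins[lap] - np.arange(1, n_anticipatory + 1), n_bins)
        ant_hits[lap] = lick_table[lap, zone].any()
    p_ant = ant_hits.mean()
    p_rand = lick_table[:, random_zone_bins].any(axis=1).mean()
    if p_ant == 0:
        return float("nan")
    return float((p_ant - p_rand) / p_ant)
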