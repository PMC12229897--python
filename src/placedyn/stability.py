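"""Multi-day place-field stability.

Tracks how place-field (PF) locations persist across a week: consistency
chains (a cell keeps a PF within a +/-30-cm window of its first-day
location on every consecutive day), transient/sustained classification,
double-exponential cohort decay fits, the memoryless-random expectation
for past-PC counts, and the bootstrap stability index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._track import circ_dist, circ_signed_diff

CHAIN_WINDOW_CM = 30.0


def pf_shift(loc_a: float, loc_b: float, track_length: float = 180.0):
    """Signed day-to-day PF shift (cm) in (-L/2, L/2]; negative = backward."""
    a = np.asarray(loc_a, dtype=float)
    b = np.asarray(loc_b, dtype=float)
    if np.any((a < 0) | (a >= track_length) | (b < 0) | (b >= track_length)):
        raise ValueError(f"PF locations must lie in [0, {track_length})")
    return circ_signed_diff(a, b, track_length)


def fit_shift_gaussian(shifts: np.ndarray, bin_cm: float = 5.0):
    """Fit a Gaussian to the shift histogram; returns (mu, sigma, 3*sigma).

    The day-to-day shift distribution is approximately normal with a
    slight backward (negative) offset; 3 s.d. of the fit sets the
    tolerance used for the consistency window.
    """
    shifts = np.asarray(shifts, dtype=float)
    if shifts.size < 50:
        raise ValueError("need >= 50 shifts for a stable Gaussian fit")
    if np.ptp(shifts) == 0:
        return float(shifts[0]), 0.0, 0.0
    edges = np.arange(-90, 90 + bin_cm, bin_cm)
    counts, edges = np.histogram(shifts, bins=edges)
    centres = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, amp, mu, sigma):
        return amp * np.exp(-((x - mu) ** 2) / (2 * sigma**2))

    p0 = (counts.max(), float(np.mean(shifts)), max(float(np.std(shifts)), bin_cm / 2))
    try:
        popt, _ = curve_fit(gauss, centres, counts, p0=p0, maxfev=10000)
    except RuntimeError as err:
        raise RuntimeError("Gaussian fit of the shift histogram failed") from err
    mu, sigma = float(popt[1]), abs(float(popt[2]))
    return mu, sigma, 3 * sigma


def build_consistency_chains(
    pf_tables: pd.DataFrame,
    window: float = CHAIN_WINDOW_CM,
    track_length: float = 180.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell consistency chains and per-cohort survivor counts.

    ``pf_tables`` is the concatenated place_fields table across days
    (columns cell, day, condition, pf_location_cm). A cohort is the set
    of cells whose first PF appearance (per condition) is on day d; the
    chain extends while the cell has a PF on every consecutive day
    within ``window`` cm (circular) of its first-day location.

    Returns (chains, cohort_counts):
      chains: cell, condition, first_day, length, locations
      cohort_counts: condition, cohort_day, day, count
    """
    chains_rows = []
    counts: dict[tuple[str, int, int], int] = {}
    for (cell, condition), grp in pf_tables.groupby(["cell", "condition"], sort=True):
        by_day = dict(zip(grp["day"].astype(int), grp["pf_location_cm"].astype(float)))
        first_day = min(by_day)
        anchor = by_day[first_day]
        length = 1
        locations = [anchor]
        day = first_day + 1
        while day in by_day and circ_dist(anchor, by_day[day], track_length) <= window:
            locations.append(by_day[day])
            length += 1
            day += 1
        chains_rows.append(
            {
                "cell": cell,
                "condition": condition,
                "first_day": first_day,
                "length": length,
                "locations": ";".join(f"{x:.1f}" for x in locations),
            }
        )
        for k in range(length):
            key = (condition, first_day, first_day + k)
            counts[key] = counts.get(key, 0) + 1
    chains = pd.DataFrame(
        chains_rows, columns=["cell", "condition", "first_day", "length", "locations"]
    )
    cohort_counts = pd.DataFrame(
        [
            {"condition": c, "cohort_day": cd, "day": d, "count": n}
            for (c, cd, d), n in sorted(counts.items())
        ],
        columns=["condition", "cohort_day", "day", "count"],
    )
    return chains, cohort_counts


def classify_cells(chains: pd.DataFrame, convention: str = "counts") -> pd.Series:
    """Transient/sustained labels from chain lengths.

    counts-convention: transient <= 2 days, sustained > 2 days.
    properties-convention: transient = 1 day, sustained > 2 days;
    2-day cells are labelled 'excluded' (minimizes classification error
    when comparing group properties).
    """
    length = chains["length"]
    if convention == "counts":
        return pd.Series(
            np.where(length > 2, "sustained", "transient"), index=chains.index
        )
    if convention == "properties":
        label = np.where(
            length > 2, "sustained", np.where(length == 1, "transient", "excluded")
        )
        return pd.Series(label, index=chains.index)
    raise ValueError("convention must be 'counts' or 'properties'")


@dataclass
class DecayFit:
    amp_fast: float
    amp_slow: float
    tau_fast: float
    tau_slow: float
    residuals: np.ndarray
    model: str = "double"     # 'single' when the double fit fails

    @property
    def mse(self) -> float:
        return float(np.mean(self.residuals**2))


def _double_exp(d, a1, a2, t1, t2):
    return a1 * np.exp(-d / t1) + a2 * np.exp(-d / t2)


def fit_double_exponential(days: np.ndarray, counts: np.ndarray) -> DecayFit:
    """Least-squares N(d) = A1 exp(-d/tau_fast) + A2 exp(-d/tau_slow).

    Taus are returned ordered (fast < slow). On non-convergence a
    single-exponential fallback is fitted and flagged via ``model``.
    """
    days = np.asarray(days, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if days.size < 5:
        raise ValueError("need >= 5 points to constrain a double exponential")
    span = max(days.max() - days.min(), 1.0)
    total = max(counts.max(), 1.0)
    starts = [
        (0.7 * total, 0.3 * total, 0.2 * span, 1.2 * span),
        (0.5 * total, 0.5 * total, 0.1 * span, 2.0 * span),
        (0.9 * total, 0.1 * total, 0.3 * span, 3.0 * span),
    ]
    bounds = ([0, 0, 1e-6, 1e-6], [np.inf, np.inf, 100 * span, 100 * span])
    best = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(
                _double_exp, days, counts, p0=p0, bounds=bounds, maxfev=20000
            )
        except RuntimeError:
            continue
        resid = counts - _double_exp(days, *popt)
        if best is None or np.sum(resid**2) < np.sum(best[1] ** 2):
            best = (popt, resid)
    if best is not None:
        (a1, a2, t1, t2), resid = best
        if t1 > t2:
            a1, a2, t1, t2 = a2, a1, t2, t1
        return DecayFit(float(a1), float(a2), float(t1), float(t2), resid)
    # fallback: single exponential
    popt, _ = curve_fit(
        lambda d, a, t: a * np.exp(-d / t),
        days,
        counts,
        p0=(total, span),
        bounds=([0, 1e-6], [np.inf, 100 * span]),
        maxfev=20000,
    )
    resid = counts - popt[0] * np.exp(-days / popt[1])
    return DecayFit(float(popt[0]), 0.0, float(popt[1]), float(popt[1]), resid, "single")


def expected_random_past_pcs(
    n_total: int = 2511,
    p_pc: float = 0.3,
    jitter_fraction: float = 60.0 / 180.0,
    n_days: int = 7,
    cohort_mode: str = "first_appearance",
    integer_counts: bool = True,
    combine_conditions: bool = True,
    decrement: str = "none",
) -> tuple[np.ndarray, float]:
    """Expected past-PC counts per day under a memoryless random process.

    Each day every available neuron becomes a PC with probability
    ``p_pc`` at a uniform random location; a past PC on day d is a cell
    whose PF chain from its first appearance is unbroken through day d,
    where a chain day requires being a PC again (``p_pc``) at a location
    inside the jitter window (``jitter_fraction`` of the track, the
    +/-30-cm window = 60/180).

    The expansion of this expectation is not unique; the knobs mirror
    the plausible readings:

    - ``cohort_mode='first_appearance'``: cohorts are first appearances,
      so day-c cohort size is A*p*(1-p)^(c-1) (availability shrinks by
      all previously recruited PCs). ``'all_active'``: every day spawns
      a cohort of A*p regardless of history.
    - ``decrement``: 'none' keeps A fixed at ``n_total``; 'accumulated'
      lowers A by the accumulated expected past-PC count.
    - ``integer_counts`` propagates expectations as whole-cell counts
      (rounded at each step).
    - ``combine_conditions`` sums the two reward conditions.

    The defaults (first-appearance cohorts, 60/180 jitter, integer
    counts, both conditions) evaluate to 490 for the study's numbers;
    the continuous expectation is 489.1 and is what
    :func:`simulate_random_past_pcs` cross-checks.

    Returns (per-day expected past counts for days 2..n_days, total).
    """
    if not (0 <= p_pc <= 1 and 0 <= jitter_fraction <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if integer_counts:
        # Whole-cell propagation, round-half-to-even; the 1e-9 pre-round
        # keeps exact .5 boundaries (e.g. survival 0.3 * 60/180 = 1/10)
        # from falling either way on float representation error.
        def step(x):
            return float(np.round(np.round(x, 9)))
    else:
        def step(x):
            return x
    past = np.zeros(n_days + 1)
    survival = p_pc * jitter_fraction
    avail = float(n_total)
    for c in range(1, n_days + 1):
        if decrement == "accumulated":
            avail = n_total - past[2:c].sum()
        elif decrement != "none":
            raise ValueError("decrement must be 'none' or 'accumulated'")
        if cohort_mode == "first_appearance":
            size = step(avail * p_pc * (1 - p_pc) ** (c - 1))
        elif cohort_mode == "all_active":
            size = step(avail * p_pc)
        else:
            raise ValueError("cohort_mode must be 'first_appearance' or 'all_active'")
        survivors = size
        for d in range(c + 1, n_days + 1):
            survivors = step(survivors * survival)
            past[d] += survivors
    per_day = past[2:]
    factor = 2.0 if combine_conditions else 1.0
    return per_day * factor, float(per_day.sum() * factor)


def simulate_random_past_pcs(
    n_total: int = 2511,
    p_pc: float = 0.3,
    jitter_fraction: float = 60.0 / 180.0,
    n_days: int = 7,
    n_replicates: int = 200,
    combine_conditions: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Monte-Carlo oracle for the memoryless past-PC expectation.

    Simulates the binary process per cell (PC with ``p_pc`` each day,
    chain survival requires a jitter-window location match with
    probability ``jitter_fraction``) and counts unbroken
    first-appearance chains, exactly mirroring the continuous
    expectation of :func:`expected_random_past_pcs`. Returns
    (mean total past count, s.e. of the mean).
    """
    rng = np.random.default_rng() if rng is None else rng
    totals = np.empty(n_replicates)
    n_cond = 2 if combine_conditions else 1
    for rep in range(n_replicates):
        total = 0
        for _ in range(n_cond):
            pc = rng.random((n_total, n_days)) < p_pc
            match = rng.random((n_total, n_days)) < jitter_fraction
            has = pc.any(axis=1)
            first = np.where(has, np.argmax(pc, axis=1), n_days)
            alive = has.copy()   # chain unbroken so far (vacuously true pre-start)
            for d in range(1, n_days):
                started = first < d
                alive &= ~started | (pc[:, d] & match[:, d])
                total += int(np.sum(alive & started))
        totals[rep] = total
    return float(totals.mean()), float(totals.std(ddof=1) / np.sqrt(n_replicates))


def count_past_new(
    pf_tables: pd.DataFrame,
    window: float = CHAIN_WINDOW_CM,
    track_length: float = 180.0,
) -> pd.DataFrame:
    """Per-day past/new PC counts and their ratio.

    A day-d PC is *past* if on any earlier day it had a PF within
    ``window`` cm (circular) of its day-d location; otherwise *new*.
    past + new = total PCs per (day, condition).
    """
    rows = []
    for condition, grp in pf_tables.groupby("condition"):
        by_day = {
            int(d): dict(zip(g["cell"], g["pf_location_cm"]))
            for d, g in grp.groupby("day")
        }
        for day in sorted(by_day):
            past = 0
            for cell, loc in by_day[day].items():
                was_past = any(
                    cell in by_day[earlier]
                    and circ_dist(by_day[earlier][cell], loc, track_length) <= window
                    for earlier in by_day
                    if earlier < day
                )
                past += int(was_past)
            total = len(by_day[day])
            new = total - past
            rows.append(
                {
                    "condition": condition,
                    "day": day,
                    "past": past,
                    "new": new,
                    "total": total,
                    "ratio": past / new if new else np.inf,
                }
            )
    return pd.DataFrame(rows, columns=["condition", "day", "past", "new", "total", "ratio"])


def stability_index(
    pf_tables: pd.DataFrame,
    day: int,
    condition: str,
    shift_window: float = 20.0,
    n_bootstrap: int = 10000,
    interval: int = 2,
    track_length: float = 180.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Per-mouse excess of low-shift PCs over a bootstrap random expectation.

    For PCs present on day d and day d+2, counts those with |shift| <
    ``shift_window`` (the first three 5-cm bins), subtracts the upper
    99% confidence bound of the same count under randomly permuted
    day-(d+2) locations, and divides by the number of PCs on day d.
    Returns NaN when fewer than 10 paired PCs exist.
    """
    rng = np.random.default_rng() if rng is None else rng
    grp = pf_tables[pf_tables["condition"] == condition]
    a = grp[grp["day"] == day].set_index("cell")["pf_location_cm"]
    b = grp[grp["day"] == day + interval].set_index("cell")["pf_location_cm"]
    common = a.index.intersection(b.index)
    n_day = len(a)
    if len(common) < 10:
        return float("nan")
    loc_a = a.loc[common].to_numpy()
    loc_b = b.loc[common].to_numpy()
    observed = int(np.sum(circ_dist(loc_a, loc_b, track_length) < shift_window))
    null = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        perm = rng.permutation(loc_b)
        null[i] = np.sum(circ_dist(loc_a, perm, track_length) < shift_window)
    ci99 = float(np.percentile(null, 99))
    return float((observed - ci99) / n_day)
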