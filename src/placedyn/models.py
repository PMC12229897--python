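"""Generative models of multi-day place-cell dynamics.

Three models of how a tracked CA1 population produces a slowly
stabilizing place-cell (PC) representation over a week:

* **Three-pool kinetic model** -- first-order competition between an
  available pool [A], a transient pool [T] and a sustained pool [S].
  Each day has an on-track activation phase (1 h, Euler dt = 0.01 h)
  during which A converts to T and S at rates k1, k2, and an off-track
  decay phase during which T and S relax back to A at rates k3 = 1/tau_fast
  and k4 = 1/tau_slow. k1 and k2 are rescaled daily by the fraction of
  the population already recruited.

* **Cascade-type state model** -- each cell occupies a state i counting
  its days of PF activity. Resting cells are either *reliable* (they
  reconstitute their PF next day with probability f = 1) or
  *unreliable* (recruited with probability p_i that grows with i).
  After an active day a cell falls to the unreliable branch with
  probability q_i (decreasing in i) and otherwise becomes reliable.
  Recruitment and PF placement are biased by track salience Sal(x) and
  by the cell's own PF history Loc(x). There are no backward
  transitions: stability only ratchets up.

* **Progressive-stabilization model** -- a single active branch whose
  escape probability decays as q_i = 0.67^i with consecutive days of
  presence; an alternative that matches daily PC counts but not the
  distribution of days with PF activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._track import circ_dist

# ---------------------------------------------------------------------------
# three-pool kinetic model


@dataclass
class ThreePoolConfig:
    """Parameters of the three-pool kinetic model.

    ``amp_fast``/``amp_slow`` are the cell-count amplitudes of the fast
    and slow components of the day-1 cohort decay; they set the k1:k2
    split. ``decay_days_per_phase`` is the amount of decay time (days)
    integrated during one off-track phase.
    """

    a0: float = 2511.0
    day1_total: float = 767.0
    amp_fast: float = 0.784 * 767.0
    amp_slow: float = 0.216 * 767.0
    tau_fast: float = 0.67       # days
    tau_slow: float = 4.6        # days
    dt_hours: float = 0.01
    activation_steps: int = 100
    decay_steps: int = 2300
    b_factor: float = 0.6        # the model's only free parameter
    expected_daily_total: float = 767.0
    decay_days_per_phase: float = 1.0


def three_pool_rates(
    day1_total: float,
    amp_fast: float,
    amp_slow: float,
    tau_fast: float,
    tau_slow: float,
    a0: float = 2511.0,
) -> tuple[float, float, float, float]:
    """Rate constants from the observed day-1 PC total and cohort decay.

    k1 + k2 = -ln((a0 - day1_total)/a0) per hour (the magnitude of the
    log of the remaining fraction, so that pools deplete during the
    activation phase), split by the fast/slow amplitude fractions;
    k3 = 1/tau_fast and k4 = 1/tau_slow per day.
    """
    if not 0 < day1_total < a0:
        raise ValueError("day1_total must lie strictly between 0 and a0")
    if tau_fast <= 0 or tau_slow <= 0:
        raise ValueError("time constants must be positive")
    ktot = -np.log((a0 - day1_total) / a0)  # per hour over the 1-h phase
    frac_fast = amp_fast / (amp_fast + amp_slow)
    k1 = ktot * frac_fast
    k2 = ktot * (1.0 - frac_fast)
    return float(k1), float(k2), 1.0 / tau_fast, 1.0 / tau_slow


def three_pool_simulate(config: ThreePoolConfig, n_days: int = 7) -> pd.DataFrame:
    """Euler integration of the three-pool model over ``n_days``.

    Returns one row per day with the pool sizes at the end of the
    activation phase (``total_pcs`` = T + S), the daily scaling factors,
    and the day-1 cohort survivor count (cohort pools subjected to decay
    only after day 1).

    [A] + [T] + [S] is conserved to machine precision throughout.
    """
    k1, k2, k3, k4 = three_pool_rates(
        config.day1_total, config.amp_fast, config.amp_slow,
        config.tau_fast, config.tau_slow, config.a0,
    )
    a, t, s = config.a0, 0.0, 0.0
    dt_act = config.dt_hours                             # hours
    dt_dec = config.decay_days_per_phase / config.decay_steps  # days
    cohort_t = cohort_s = None
    rows = []
    for day in range(1, n_days + 1):
        scale_a = 1.0 - (t + s) / config.expected_daily_total
        scale_b = scale_a * config.b_factor
        k1_d, k2_d = k1 * scale_a, k2 * scale_b
        for _ in range(config.activation_steps):
            flux1 = k1_d * a * dt_act
            flux2 = k2_d * a * dt_act
            a -= flux1 + flux2
            t += flux1
            s += flux2
            if a < 0:
                raise FloatingPointError("available pool went negative; reduce dt")
        if cohort_t is None:
            cohort_t, cohort_s = t, s
        rows.append(
            {
                "day": day,
                "A": a,
                "T": t,
                "S": s,
                "total_pcs": t + s,
                "scale_a": scale_a,
                "scale_b": scale_b,
                "day1_cohort_survivors": cohort_t + cohort_s,
            }
        )
        for _ in range(config.decay_steps):
            flux3 = k3 * t * dt_dec
            flux4 = k4 * s * dt_dec
            t -= flux3
            s -= flux4
            a += flux3 + flux4
            cohort_t -= k3 * cohort_t * dt_dec
            cohort_s -= k4 * cohort_s * dt_dec
    return pd.DataFrame(rows)


def three_pool_fit_b(
    config: ThreePoolConfig,
    observed: np.ndarray,
    n_days: int = 7,
    grid: np.ndarray | None = None,
) -> tuple[float, np.ndarray, float]:
    """Fit the free parameter b (the k2 scaling multiplier).

    ``observed`` is an (n_days, 2) array of [T, S] pool counts at the
    end of each day's activation phase. A coarse grid scan is refined
    by a bounded scalar minimization of the mean squared error over the
    2 * n_days points. Returns (b, residuals, mse).
    """
    from scipy.optimize import minimize_scalar

    observed = np.asarray(observed, dtype=float)

    def run(b: float) -> np.ndarray:
        cfg = ThreePoolConfig(**{**config.__dict__, "b_factor": float(b)})
        out = three_pool_simulate(cfg, n_days=n_days)
        return out[["T", "S"]].to_numpy()

    def mse(b: float) -> float:
        return float(np.mean((run(b) - observed) ** 2))

    if grid is None:
        grid = np.linspace(0.05, 2.0, 40)
    b0 = grid[int(np.argmin([mse(b) for b in grid]))]
    lo = max(b0 - 0.1, 1e-3)
    res = minimize_scalar(mse, bounds=(lo, b0 + 0.1), method="bounded")
    b_best = float(res.x)
    resid = (run(b_best) - observed).ravel()
    return b_best, resid, float(np.mean(resid**2))


# ---------------------------------------------------------------------------
# cascade-type state model


@dataclass
class CascadeConfig:
    """Printed coefficients of the cascade state model.

    q_i = q_amp * exp(-q_rate * (i - 1)) + q_floor;
    alpha_i = alpha_coef * (1 - q_i)^2;
    beta_k = b1 * exp(-r1 * (k - 1)) + b2 * exp(-r2 * (k - 1));
    gamma_l = (1 + min(l/6, 1)) / (1 - 0.5 * min(l/6, 1)).
    """

    n_cells: int = 2511
    n_days: int = 7
    n_bins: int = 50
    track_length: float = 180.0
    delta: float = 1.7
    salience_zones: tuple = ((30.0, 60.0), (120.0, 150.0))
    loc_window_cm: float = 30.0
    init_state1_fraction: float = 0.12
    f_reliable: float = 1.0
    q_amp: float = 0.5353
    q_rate: float = 0.3327
    q_floor: float = 0.2912
    alpha_coef: float = 6.6259
    beta_params: tuple = (0.4927, 0.1289, 0.7032, 1.1846)
    indexing: str = "destination"   # or "source"
    printed_loc_normalization: bool = False
    n_replicates: int = 1000

    def q(self, i):
        return self.q_amp * np.exp(-self.q_rate * (np.asarray(i, float) - 1)) + self.q_floor

    def alpha(self, i):
        return self.alpha_coef * (1 - self.q(i)) ** 2

    def beta(self, k):
        b1, r1, b2, r2 = self.beta_params
        return b1 * np.exp(-r1 * (k - 1)) + b2 * np.exp(-r2 * (k - 1))

    @staticmethod
    def gamma(l):
        m = np.minimum(np.asarray(l, float) / 6.0, 1.0)
        return (1 + m) / (1 - 0.5 * m)

    def bin_positions(self) -> np.ndarray:
        # x_j = j * L / N for j = 1..N
        return np.arange(1, self.n_bins + 1) * self.track_length / self.n_bins


def salience_weights(config: CascadeConfig) -> np.ndarray:
    """Sal(x_j): delta inside salience zones, normalized to track-average 1.

    The normalization uses the actual fraction s of bins inside the
    zones, so mean(Sal) over the track equals 1 exactly.
    """
    xs = config.bin_positions()
    in_zone = np.zeros(config.n_bins, dtype=bool)
    for a, b in config.salience_zones:
        in_zone |= (xs >= a) & (xs <= b)
    s = in_zone.mean()
    return np.where(in_zone, config.delta, 1.0) / (1 + (config.delta - 1) * s)


def history_weights(
    config: CascadeConfig, prev_bin: int | None, days_sustained: float
) -> np.ndarray:
    """Loc(x_j): gamma within 30 cm of the previous PF, average-1 normalized.

    ``prev_bin`` is the 0-based bin of the previously sustained PF, or
    None (Loc = 1 everywhere). gamma grows with the number of days the
    previous PF was sustained. With ``printed_loc_normalization`` the
    constant 1/(1 + (gamma-1)/3) is used instead of the exact bin
    fraction.
    """
    if prev_bin is None:
        return np.ones(config.n_bins)
    xs = config.bin_positions()
    g = float(config.gamma(days_sustained))
    near = circ_dist(xs, xs[int(prev_bin)], config.track_length) <= config.loc_window_cm
    frac = 1.0 / 3.0 if config.printed_loc_normalization else near.mean()
    return np.where(near, g, 1.0) / (1 + (g - 1) * frac)


def salience_and_history_weights(
    config: CascadeConfig, prev_bin: int | None = None, days_sustained: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """(Sal, Loc) weight profiles over the spatial bins."""
    return salience_weights(config), history_weights(config, prev_bin, days_sustained)


def _cascade_tables(config: CascadeConfig, max_state: int):
    """Per-state recruitment weight tensor W[i, pb+1, j] = Sal_j * Loc_j.

    Index 0 of the second axis is 'no previous PF' (Loc = 1).
    """
    sal = salience_weights(config)
    n = config.n_bins
    w = np.empty((max_state + 1, n + 1, n))
    for i in range(max_state + 1):
        w[i, 0] = sal
        for pb in range(n):
            w[i, pb + 1] = sal * history_weights(config, pb, days_sustained=i)
    return w


def _alpha_for_transition(config: CascadeConfig, resting_state: np.ndarray):
    i = np.asarray(resting_state, float)
    if config.indexing == "destination":
        return config.alpha(i + 1)
    if config.indexing == "source":
        return config.alpha(np.maximum(i, 1))
    raise ValueError("indexing must be 'destination' or 'source'")


def _q_for_decay(config: CascadeConfig, active_state: np.ndarray):
    s = np.asarray(active_state, float)
    if config.indexing == "destination":
        return config.q(s)
    return config.q(np.maximum(s - 1, 1))


@dataclass
class StateModelResult:
    """Per-replicate logs of a state-model simulation.

    ``active``: (n_replicates, n_cells, n_days) bool;
    ``location``: same shape, PF bin while active (-1 otherwise);
    ``counts``: (n_replicates, n_days) daily active-PC counts.
    """

    active: np.ndarray
    location: np.ndarray
    counts: np.ndarray
    model: str = "cascade"

    @property
    def mean_daily_count(self) -> float:
        return float(self.counts.mean())


def cascade_simulate(
    config: CascadeConfig,
    rng: np.random.Generator | None = None,
    n_replicates: int | None = None,
) -> StateModelResult:
    """Monte-Carlo simulation of the cascade state model.

    Cells start 88% in unreliable state 0 and 12% in unreliable state 1
    (a training effect). Each day: reliable cells reconstitute their PF
    (f = 1); unreliable cells at state i are recruited with
    p_i = 1 - prod_j (1 - r_{i,k} Sal(x_j) Loc(x_j)), where
    r_{i,k} = 1 - (1 - alpha beta_k)^(1/N); recruited cells draw a PF
    bin from Pr(j) proportional to Sal Loc. Active cells then fall to
    the unreliable branch with probability q and otherwise become
    reliable. alpha*beta is clamped to [0, 1) before the N-th root.
    """
    rng = np.random.default_rng() if rng is None else rng
    reps = config.n_replicates if n_replicates is None else n_replicates
    n, days, nbins = config.n_cells, config.n_days, config.n_bins
    max_state = days + 1
    w = _cascade_tables(config, max_state)
    states_axis = np.arange(max_state + 1)

    active_log = np.zeros((reps, n, days), dtype=bool)
    loc_log = np.full((reps, n, days), -1, dtype=np.int16)
    counts = np.zeros((reps, days), dtype=np.int64)

    n_state1 = int(round(config.init_state1_fraction * n))
    for rep in range(reps):
        state = np.zeros(n, dtype=np.int16)
        state[:n_state1] = 1
        reliable = np.zeros(n, dtype=bool)
        prev = np.full(n, -1, dtype=np.int16)   # last PF bin, -1 = none
        for k in range(1, days + 1):
            beta_k = float(config.beta(k))
            ab = np.clip(_alpha_for_transition(config, states_axis) * beta_k, 0.0, 1 - 1e-12)
            r = 1 - (1 - ab) ** (1.0 / nbins)
            # p table over (state, prev-bin-index); prev index 0 = none
            fail = np.prod(1 - r[:, None, None] * w, axis=2)  # (S+1, nbins+1)
            p_table = 1 - fail
            cum = np.cumsum(r[:, None, None] * w, axis=2)
            total = cum[:, :, -1:]
            cum = np.divide(cum, total, out=np.zeros_like(cum), where=total > 0)

            pbi = prev + 1
            active = reliable.copy()
            newloc = prev.copy()
            unrel = ~reliable
            u = rng.random(n)
            recruited = unrel & (u < p_table[state, pbi])
            idx = np.flatnonzero(recruited)
            if idx.size:
                rows = cum[state[idx], pbi[idx]]
                draws = rng.random(idx.size)
                newloc[idx] = (rows < draws[:, None]).sum(axis=1).astype(np.int16)
            active |= recruited
            state = state + active.astype(np.int16)
            prev = np.where(active, newloc, prev).astype(np.int16)

            active_log[rep, :, k - 1] = active
            loc_log[rep, :, k - 1] = np.where(active, prev, -1)
            counts[rep, k - 1] = int(active.sum())

            drop = rng.random(n) < _q_for_decay(config, state)
            reliable = active & ~drop
    return StateModelResult(active_log, loc_log, counts, model="cascade")


def cascade_enumerate(config: CascadeConfig) -> np.ndarray:
    """Exact expected daily active-PC fraction by state-space enumeration.

    Propagates the full probability distribution over
    (state, reliable-flag, previous-PF bin) through the daily two-phase
    update -- an exhaustive Markov-chain computation usable as an
    independent check of the Monte-Carlo simulation at small n.
    Returns the expected active fraction per day.
    """
    n_bins, days = config.n_bins, config.n_days
    max_state = days + 1
    w = _cascade_tables(config, max_state)
    # realized initial split: the simulation rounds to whole cells
    frac1 = round(config.init_state1_fraction * config.n_cells) / config.n_cells
    # mass[flag, state, pb_index]; flag 0 = unreliable, 1 = reliable
    mass = np.zeros((2, max_state + 2, n_bins + 1))
    mass[0, 0, 0] = 1 - frac1
    mass[0, 1, 0] = frac1
    states_axis = np.arange(max_state + 1)
    expected = np.zeros(days)
    for k in range(1, days + 1):
        beta_k = float(config.beta(k))
        ab = np.clip(_alpha_for_transition(config, states_axis) * beta_k, 0.0, 1 - 1e-12)
        r = 1 - (1 - ab) ** (1.0 / n_bins)
        fail = np.prod(1 - r[:, None, None] * w, axis=2)
        p_table = 1 - fail
        loc_pr = r[:, None, None] * w
        loc_pr = loc_pr / loc_pr.sum(axis=2, keepdims=True)

        new_mass = np.zeros_like(mass)
        active_mass = np.zeros((max_state + 2, n_bins + 1))
        for i in range(max_state + 1):
            # unreliable, not recruited: stay put
            stay = mass[0, i] * (1 - p_table[i])
            new_mass[0, i] += stay
            # unreliable, recruited to state i+1 with fresh location
            rec = mass[0, i] * p_table[i]
            if rec.sum() > 0:
                dist = rec @ loc_pr[i]          # (n_bins,) over new locations
                active_mass[i + 1, 1:] += dist
            # reliable: reconstitute in place
            active_mass[i + 1] += mass[1, i] * config.f_reliable
            new_mass[0, i] += mass[1, i] * (1 - config.f_reliable)
        expected[k - 1] = active_mass.sum()
        q = _q_for_decay(config, np.arange(max_state + 2))
        new_mass[0] += active_mass * q[:, None]
        new_mass[1] += active_mass * (1 - q[:, None])
        mass = new_mass
    return expected


# ---------------------------------------------------------------------------
# progressive-stabilization model


@dataclass
class ProgressiveConfig:
    """Alternate model: stability grows only with consecutive presence."""

    n_cells: int = 2511
    n_days: int = 7
    n_bins: int = 50
    p1_coef: float = 0.3186        # p1 = p1_coef * beta_k
    q_base: float = 0.67           # q_i = q_base ** i
    f_active: float = 1.0
    beta_params: tuple = (0.4927, 0.1289, 0.7032, 1.1846)
    n_replicates: int = 1000

    def beta(self, k):
        b1, r1, b2, r2 = self.beta_params
        return b1 * np.exp(-r1 * (k - 1)) + b2 * np.exp(-r2 * (k - 1))

    def q(self, i):
        return self.q_base ** np.asarray(i, float)


def progressive_simulate(
    config: ProgressiveConfig,
    rng: np.random.Generator | None = None,
    n_replicates: int | None = None,
) -> StateModelResult:
    """Simulate the progressive-stabilization model.

    'no PF' cells enter active state 1 with p1 = 0.3186 * beta_k at a
    uniformly random location; active cells at state i advance to i + 1
    keeping their PF (f = 1) and then revert to 'no PF' with
    q_i = 0.67^i. A single miss resets stability entirely.
    """
    rng = np.random.default_rng() if rng is None else rng
    reps = config.n_replicates if n_replicates is None else n_replicates
    n, days = config.n_cells, config.n_days
    active_log = np.zeros((reps, n, days), dtype=bool)
    loc_log = np.full((reps, n, days), -1, dtype=np.int16)
    counts = np.zeros((reps, days), dtype=np.int64)
    for rep in range(reps):
        state = np.zeros(n, dtype=np.int16)    # 0 = no PF
        loc = np.full(n, -1, dtype=np.int16)
        for k in range(1, days + 1):
            p1 = float(np.clip(config.p1_coef * config.beta(k), 0, 1))
            entering = (state == 0) & (rng.random(n) < p1)
            staying = state > 0
            loc[entering] = rng.integers(0, config.n_bins, entering.sum(), dtype=np.int16)
            state = np.where(entering | staying, state + 1, state).astype(np.int16)
            active = entering | staying
            active_log[rep, :, k - 1] = active
            loc_log[rep, :, k - 1] = np.where(active, loc, -1)
            counts[rep, k - 1] = int(active.sum())
            revert = active & (rng.random(n) < config.q(state))
            state[revert] = 0
            loc[revert] = -1
    return StateModelResult(active_log, loc_log, counts, model="progressive")


# ---------------------------------------------------------------------------
# summaries shared by the state models


def days_active_distribution(result: StateModelResult) -> pd.DataFrame:
    """Proportion of cells with PF activity on n = 0..n_days days.

    Mean and s.e.m. over replicates.
    """
    n_days = result.active.shape[2]
    per_cell = result.active.sum(axis=2)                 # (reps, cells)
    reps = per_cell.shape[0]
    props = np.stack(
        [(per_cell == n).mean(axis=1) for n in range(n_days + 1)], axis=1
    )
    return pd.DataFrame(
        {
            "days_active": np.arange(n_days + 1),
            "proportion": props.mean(axis=0),
            "sem": props.std(axis=0, ddof=1) / np.sqrt(reps) if reps > 1 else 0.0,
        }
    )


def reappearance_probability(result: StateModelResult, max_prior: int = 5) -> pd.DataFrame:
    """P(PF re-forms after exactly one missed day), by prior days active.

    Pools (cell, day) observations where the cell was inactive on day d
    but had m prior active days; the probability is of being active on
    day d + 1. Mean and s.e.m. over replicates.
    """
    act = result.active
    reps, _, days = act.shape
    probs = np.full((reps, max_prior + 1), np.nan)
    for rep in range(reps):
        a = act[rep]
        prior = np.cumsum(a, axis=1)
        for m in range(1, max_prior + 1):
            num = den = 0
            for d in range(1, days - 1):
                sel = (~a[:, d]) & (prior[:, d - 1] == m)
                den += int(sel.sum())
                num += int((sel & a[:, d + 1]).sum())
            probs[rep, m] = num / den if den else np.nan
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(probs, axis=0)
        sem = np.nanstd(probs, axis=0, ddof=1) / np.sqrt(reps) if reps > 1 else 0 * mean
    return pd.DataFrame(
        {"prior_days_active": np.arange(max_prior + 1), "p_reappear": mean, "sem": sem}
    ).iloc[1:]


def sustained_transient_counts(
    result: StateModelResult,
    window_bins: int = 8,
    n_bins: int = 50,
) -> pd.DataFrame:
    """Daily sustained vs transient active-PC counts from model logs.

    A cell's consistency chain runs from its first active day while it
    stays active on consecutive days with its PF within ``window_bins``
    (circular) of the first day's bin; chains > 2 days are sustained.
    A day-d active cell counts under its chain's class while day d is
    inside the chain, and as transient otherwise.
    """
    act, loc = result.active, result.location
    reps, n_cells, days = act.shape
    sustained = np.zeros((reps, days))
    transient = np.zeros((reps, days))
    for rep in range(reps):
        a, l = act[rep], loc[rep]
        ever = a.any(axis=1)
        first = np.where(ever, np.argmax(a, axis=1), days)
        anchor = l[np.arange(n_cells), np.minimum(first, days - 1)]
        length = np.where(ever, 1, 0)
        alive = ever.copy()
        for d in range(days):
            started = first < d
            if d > 0:
                raw = np.abs(l[:, d].astype(int) - anchor.astype(int))
                dist = np.minimum(raw, n_bins - raw)
                ok = a[:, d] & (dist <= window_bins)
                alive &= ~started | ok
                length += (alive & started).astype(int)
        cls_sustained = length > 2
        for d in range(days):
            in_chain = a[:, d] & (first <= d) & (first + length > d)
            sustained[rep, d] = np.sum(in_chain & cls_sustained)
            transient[rep, d] = np.sum(a[:, d]) - sustained[rep, d]
    rows = []
    for d in range(days):
        rows.append(
            {
                "day": d + 1,
                "sustained_mean": sustained[:, d].mean(),
                "transient_mean": transient[:, d].mean(),
                "sustained_sem": sustained[:, d].std(ddof=1) / np.sqrt(reps) if reps > 1 else 0.0,
                "transient_sem": transient[:, d].std(ddof=1) / np.sqrt(reps) if reps > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def model_pf_density(result: StateModelResult, n_bins: int = 50) -> np.ndarray:
    """Mean PF count per bin per day over replicates."""
    locs = result.location[result.active]
    reps, _, days = result.active.shape
    return np.bincount(locs, minlength=n_bins) / (reps * days)


def cascade_summaries(result: StateModelResult) -> dict:
    """Bundle the standard state-model summaries."""
    return {
        "days_active": days_active_distribution(result),
        "reappearance": reappearance_probability(result),
        "sustained_transient": sustained_transient_counts(result),
        "pf_density": model_pf_density(result),
        "mean_daily_count": result.mean_daily_count,
    }
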