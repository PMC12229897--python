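"""The three generative models of week-long place-cell dynamics.

Runs the three-pool kinetic model (population level), the cascade
state model (per-cell, history-dependent) and the progressive-
stabilization alternative, and prints the quantities each one is
judged on.
"""

import numpy as np

from placedyn import models, stability

# three-pool: pools [A]vailable -> [T]ransient/[S]ustained by day
tp = models.three_pool_simulate(models.ThreePoolConfig(), n_days=7)
print("three-pool daily PC counts (T+S):",
      np.round(tp["total_pcs"].to_numpy(), 1))
fit = stability.fit_double_exponential(
    tp["day"].to_numpy(float), tp["day1_cohort_survivors"].to_numpy())
print(f"day-1 cohort refit: tau_fast = {fit.tau_fast:.2f} d, "
      f"tau_slow = {fit.tau_slow:.2f} d (configured: 0.67 / 4.6)")

# cascade: stability ratchets up with each day of place-field activity
rng = np.random.default_rng(0)
cas = models.cascade_simulate(models.CascadeConfig(n_replicates=100), rng=rng)
print(f"\ncascade mean daily PC count over 100 replicates: "
      f"{cas.mean_daily_count:.1f} (study: 767 +/- 8)")
summ = models.cascade_summaries(cas)
print("reappearance probability after one missed day, by prior days active:")
print(summ["reappearance"].round(3).to_string(index=False))
print("(rising with history: past activity begets future activity)")

# progressive: stability grows only through consecutive presence
prog = models.progressive_simulate(models.ProgressiveConfig(n_replicates=100),
                                   rng=rng)
d_cas = models.days_active_distribution(cas)
d_prog = models.days_active_distribution(prog)
print("\nproportion of cells active exactly n days (n = 1..7):")
print("  cascade    :", np.round(d_cas["proportion"].to_numpy()[1:], 3))
print("  progressive:", np.round(d_prog["proportion"].to_numpy()[1:], 3))
print("the two models are distinguishable from this distribution even at "
      "matched daily totals.")
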