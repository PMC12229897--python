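"""Day-to-day shifts, chains, cohort decay fits and random expectations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from placedyn import stability


class TestPfShift:
    def test_zero_shift(self):
        assert stability.pf_shift(50.0, 50.0) == 0.0

    def test_wraps_forward_across_lap_boundary(self):
        assert stability.pf_shift(170.0, 10.0) == pytest.approx(20.0)

    def test_backward_shift_is_negative(self):
        assert stability.pf_shift(100.0, 95.0) == pytest.approx(-5.0)

    @settings(deadline=None, derandomize=True)
    @given(
        a=st.floats(0, 179.99),
        b=st.floats(0, 179.99),
    )
    def test_antisymmetry(self, a, b):
        s1 = stability.pf_shift(a, b)
        if abs(s1) == 90.0:  # the boundary maps to +90 in both directions
            return
        assert stability.pf_shift(b, a) == pytest.approx(-s1, abs=1e-9)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            stability.pf_shift(-1.0, 20.0)


class TestShiftGaussian:
    def test_recovers_study_scale_parameters(self, rng):
        # 3 s.d. of the fitted day-to-day shift distribution ~ 25 cm
        shifts = rng.normal(-1.0, 25.0 / 3.0, 5000)
        mu, sigma, three_sd = stability.fit_shift_gaussian(shifts)
        assert three_sd == pytest.approx(25.0, rel=0.10)
        assert mu == pytest.approx(-1.0, abs=1.0)

    def test_recovers_arbitrary_parameters(self, rng):
        shifts = rng.normal(4.0, 12.0, 1000)
        mu, sigma, _ = stability.fit_shift_gaussian(shifts)
        assert mu == pytest.approx(4.0, abs=1.5)
        assert sigma == pytest.approx(12.0, rel=0.15)

    def test_delta_distribution(self):
        mu, sigma, three_sd = stability.fit_shift_gaussian(np.zeros(100))
        assert sigma == 0.0


def pf_table(rows):
    return pd.DataFrame(rows, columns=["cell", "day", "condition", "pf_location_cm"])


class TestChains:
    def test_static_cells_survive_all_days(self):
        rows = [
            (c, d, "RL1", 36.0) for c in range(5) for d in range(1, 4)
        ]
        chains, counts = stability.build_consistency_chains(pf_table(rows))
        assert (chains["length"] == 3).all()
        day_counts = counts[counts.cohort_day == 1].sort_values("day")["count"]
        assert day_counts.tolist() == [5, 5, 5]

    def test_chain_breaks_outside_window(self):
        rows = [(0, 1, "RL1", 10.0), (0, 2, "RL1", 41.0)]  # distance 31 cm
        chains, _ = stability.build_consistency_chains(pf_table(rows), window=30.0)
        assert chains.loc[0, "length"] == 1

    def test_chain_continues_inside_window(self):
        rows = [(0, 1, "RL1", 10.0), (0, 2, "RL1", 39.0)]
        chains, _ = stability.build_consistency_chains(pf_table(rows), window=30.0)
        assert chains.loc[0, "length"] == 2

    def test_missed_day_ends_chain(self):
        rows = [(0, 1, "RL1", 10.0), (0, 3, "RL1", 10.0)]
        chains, _ = stability.build_consistency_chains(pf_table(rows))
        assert chains.loc[0, "length"] == 1

    def test_tighter_window_never_increases_counts(self, rng):
        rows = [
            (c, d, "RL1", float(rng.uniform(0, 180)))
            for c in range(40)
            for d in range(1, 5)
            if rng.random() < 0.8
        ]
        _, c30 = stability.build_consistency_chains(pf_table(rows), window=30.0)
        _, c20 = stability.build_consistency_chains(pf_table(rows), window=20.0)
        merged = c30.merge(
            c20, on=["condition", "cohort_day", "day"], how="left", suffixes=("_30", "_20")
        ).fillna(0)
        assert (merged["count_20"] <= merged["count_30"]).all()

    def test_cohort_counts_non_increasing(self, analyzed_day1, small_experiment):
        _, sessions, _ = small_experiment
        from placedyn.pipeline import analyze_session

        _, pf1, _, _ = analyzed_day1
        _, pf2, _ = analyze_session(sessions[1], n_shuffles=150, rng=np.random.default_rng(5))
        _, counts = stability.build_consistency_chains(
            pd.concat([pf1, pf2], ignore_index=True)
        )
        for (_, _), grp in counts.groupby(["condition", "cohort_day"]):
            seq = grp.sort_values("day")["count"].tolist()
            assert seq == sorted(seq, reverse=True)


class TestClassification:
    @pytest.mark.parametrize(
        "length,counts_label,props_label",
        [(1, "transient", "transient"), (2, "transient", "excluded"), (3, "sustained", "sustained")],
    )
    def test_conventions(self, length, counts_label, props_label):
        chains = pd.DataFrame({"length": [length]})
        assert stability.classify_cells(chains, "counts")[0] == counts_label
        assert stability.classify_cells(chains, "properties")[0] == props_label


class TestDoubleExponential:
    def test_recovers_study_taus_within_5_percent(self):
        days = np.arange(1, 8, dtype=float)
        counts = 300 * np.exp(-days / 0.67) + 150 * np.exp(-days / 4.6)
        fit = stability.fit_double_exponential(days, counts)
        assert fit.tau_fast == pytest.approx(0.67, rel=0.05)
        assert fit.tau_slow == pytest.approx(4.6, rel=0.05)
        assert fit.tau_fast < fit.tau_slow

    def test_pure_single_exponential_nests(self):
        days = np.arange(1, 9, dtype=float)
        counts = 200 * np.exp(-days / 2.0)
        fit = stability.fit_double_exponential(days, counts)
        # one amplitude vanishes or both taus collapse onto 2.0
        small_amp = min(fit.amp_fast, fit.amp_slow) < 0.05 * 200
        taus_equal = fit.tau_fast == pytest.approx(2.0, rel=0.1) and fit.tau_slow == pytest.approx(2.0, rel=0.1)
        assert small_amp or taus_equal
        assert fit.mse < 1e-6


class TestRandomExpectation:
    def test_zero_pc_probability_gives_zero(self):
        per_day, total = stability.expected_random_past_pcs(p_pc=0.0)
        assert total == 0.0 and np.all(per_day == 0)

    def test_study_defaults_total(self):
        _, total = stability.expected_random_past_pcs()
        assert total == 490.0

    def test_monte_carlo_agrees_with_continuous_expectation(self, rng):
        _, expected = stability.expected_random_past_pcs(integer_counts=False)
        mc, se = stability.simulate_random_past_pcs(n_replicates=60, rng=rng)
        assert abs(mc - expected) < 3 * se


class TestPastNew:
    def test_day_one_all_new(self):
        rows = [(c, 1, "RL1", 10.0 * c) for c in range(5)]
        out = stability.count_past_new(pf_table(rows))
        assert out.iloc[0]["past"] == 0 and out.iloc[0]["new"] == 5

    def test_static_population_all_past_after_day_one(self):
        rows = [(c, d, "RL1", 20.0 * c % 180) for c in range(4) for d in (1, 2, 3)]
        out = stability.count_past_new(pf_table(rows)).set_index("day")
        assert out.loc[2, "past"] == 4 and out.loc[3, "past"] == 4

    def test_crafted_example_matches_hand_enumeration(self):
        rows = [
            (0, 1, "RL1", 10.0), (1, 1, "RL1", 50.0), (2, 1, "RL1", 90.0),
            # day 2: cell0 within 30 of day1 (past); cell1 moved 40 cm (new);
            # cell3 brand new; cell2 absent
            (0, 2, "RL1", 30.0), (1, 2, "RL1", 90.0), (3, 2, "RL1", 130.0),
            # day 3: cell1 matches its day-2 location (past); cell2 returns
            # at its day-1 location (past); cell4 new
            (1, 3, "RL1", 95.0), (2, 3, "RL1", 91.0), (4, 3, "RL1", 170.0),
        ]
        out = stability.count_past_new(pf_table(rows)).set_index("day")
        assert out.loc[2, ["past", "new"]].tolist() == [1, 2]
        assert out.loc[3, ["past", "new"]].tolist() == [2, 1]
        assert (out["past"] + out["new"] == out["total"]).all()


class TestStabilityIndex:
    def test_random_locations_give_near_zero_or_negative(self, rng):
        rows = [
            (c, d, "RL1", float(rng.uniform(0, 180)))
            for c in range(120)
            for d in (1, 3)
        ]
        idx = stability.stability_index(
            pf_table(rows), day=1, condition="RL1", n_bootstrap=1500, rng=rng
        )
        assert idx < 0.05

    def test_static_population_is_strongly_positive(self, rng):
        rows = [(c, d, "RL1", float(1.5 * c) % 180) for c in range(120) for d in (1, 3)]
        idx = stability.stability_index(
            pf_table(rows), day=1, condition="RL1", n_bootstrap=1500, rng=rng
        )
        assert idx > 0.5

    def test_reproducible_under_fixed_seed(self, rng):
        rows = [
            (c, d, "RL1", float((7 * c + 3 * d) % 180)) for c in range(50) for d in (1, 3)
        ]
        i1 = stability.stability_index(
            pf_table(rows), 1, "RL1", n_bootstrap=500, rng=np.random.default_rng(4)
        )
        i2 = stability.stability_index(
            pf_table(rows), 1, "RL1", n_bootstrap=500, rng=np.random.default_rng(4)
        )
        assert i1 == i2

    def test_too_few_cells_flagged(self):
        rows = [(c, d, "RL1", 10.0) for c in range(5) for d in (1, 3)]
        assert np.isnan(stability.stability_index(pf_table(rows), 1, "RL1", n_bootstrap=100))
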