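"""Comparative statistics: class fractions, arm association, the two
significance tests, and the coefficient of exchange."""

import itertools
from math import sqrt

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ndjmap.stats import (
    arm_association,
    co_class_fractions,
    coefficient_of_exchange,
    cross_chromosome_co_comparison,
    mann_whitney_test,
    two_proportion_z_test,
    zero_co_chromosome_fraction,
)


def arm_counts_frame(rows):
    return pd.DataFrame(rows, columns=["event", "event_class", "arm", "n_co"])


class TestCoClassFractions:
    def _mii_table(self, n_single=4, n_total=10):
        rows = [(f"e{i}", "MII", "L", 1) for i in range(n_single)]
        rows += [(f"e{i}", "MII", "L", 0) for i in range(n_single, n_total)]
        return arm_counts_frame(rows)

    def test_mii_single_fraction_halved(self):
        table = co_class_fractions(self._mii_table(4, 10), adjust_mii=True)
        row = table[(table["event_class"] == "MII") & (table["n_co"] == 1)].iloc[0]
        assert row["fraction"] == pytest.approx(0.4)
        assert row["fraction_adjusted"] == pytest.approx(0.2)

    def test_adjust_off_identity(self):
        table = co_class_fractions(self._mii_table(4, 10), adjust_mii=False)
        row = table[(table["event_class"] == "MII") & (table["n_co"] == 1)].iloc[0]
        assert row["fraction_adjusted"] == row["fraction"] == pytest.approx(0.4)

    def test_double_co_fraction_never_adjusted(self):
        rows = [("e0", "MII", "L", 2), ("e1", "MII", "L", 2), ("e2", "MII", "L", 0)]
        table = co_class_fractions(arm_counts_frame(rows), adjust_mii=True)
        row = table[(table["event_class"] == "MII") & (table["n_co"] == 2)].iloc[0]
        assert row["fraction_adjusted"] == row["fraction"] == pytest.approx(2 / 3)

    def test_raw_fractions_sum_to_one_per_class(self):
        rows = [(f"e{i}", cls, arm, int(np.random.default_rng(i).integers(0, 3)))
                for i, cls in enumerate(["MI"] * 20 + ["MII"] * 10) for arm in ("L", "R")]
        table = co_class_fractions(arm_counts_frame(rows))
        for _, sub in table.groupby("event_class"):
            assert sub["fraction"].sum() == pytest.approx(1.0)

    def test_mi_class_not_touched_by_adjustment(self):
        rows = [("e0", "MI", "L", 1), ("e1", "MI", "L", 0)]
        table = co_class_fractions(arm_counts_frame(rows), adjust_mii=True)
        assert (table["fraction_adjusted"] == table["fraction"]).all()


class TestZeroCoChromosomes:
    def test_printed_mi_fraction(self):
        """20 of 49 MI chromosomes with no calls on either arm = 40.8%."""
        rows = []
        for i in range(49):
            n_l = 0 if i < 20 else (1 if i < 45 else 2)
            n_r = 0 if i < 33 else 1
            rows += [(f"e{i}", "MI", "L", n_l), (f"e{i}", "MI", "R", n_r)]
        frac = zero_co_chromosome_fraction(arm_counts_frame(rows))
        assert frac == pytest.approx(20 / 49)
        assert round(100 * frac, 1) == 40.8

    def test_all_zero(self):
        rows = [("e0", "MI", "L", 0), ("e0", "MI", "R", 0)]
        assert zero_co_chromosome_fraction(arm_counts_frame(rows)) == 1.0

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            zero_co_chromosome_fraction(arm_counts_frame([]))


class TestArmAssociation:
    def test_hand_tabulated(self):
        rows = []
        # 4 events left=0: 1 of 4 has a right CO; 6 events left>=1: 3 of 6
        for i in range(4):
            rows += [(f"a{i}", "MI", "L", 0), (f"a{i}", "MI", "R", 1 if i == 0 else 0)]
        for i in range(6):
            rows += [(f"b{i}", "MI", "L", 1), (f"b{i}", "MI", "R", 1 if i < 3 else 0)]
        table = arm_association(arm_counts_frame(rows), "L", "R")
        at = table.set_index("condition")
        assert at.loc["left_0", "p_right_co"] == pytest.approx(0.25)
        assert at.loc["left_0", "n"] == 4
        assert at.loc["left_1plus", "p_right_co"] == pytest.approx(0.5)
        assert at.loc["left_1plus", "n"] == 6

    def test_all_events_both_arms(self):
        rows = []
        for i in range(5):
            rows += [(f"e{i}", "MI", "L", 1), (f"e{i}", "MI", "R", 2)]
        table = arm_association(arm_counts_frame(rows), "L", "R")
        at = table.set_index("condition")
        assert at.loc["left_1plus", "p_right_co"] == 1.0
        assert at.loc["left_0", "n"] == 0

    def test_independent_arms_equal_conditionals(self):
        rng = np.random.default_rng(11)
        rows = []
        for i in range(4000):
            rows += [(f"e{i}", "MI", "L", int(rng.random() < 0.5)),
                     (f"e{i}", "MI", "R", int(rng.random() < 0.5))]
        at = arm_association(arm_counts_frame(rows), "L", "R").set_index("condition")
        p0, p1 = at.loc["left_0", "p_right_co"], at.loc["left_1plus", "p_right_co"]
        se = sqrt(0.25 / at.loc["left_0", "n"] + 0.25 / at.loc["left_1plus", "n"])
        assert abs(p0 - p1) < 3 * se


def yates_chi2_oracle(x1, n1, x2, n2, correction=True):
    """Textbook 2x2 chi-square with Yates correction, coded independently
    of the z-test implementation."""
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expect = row @ col / table.sum()
    adj = np.abs(table - expect)
    if correction:
        adj = np.maximum(adj - 0.5, 0.0)
    chi2 = float((adj**2 / expect).sum())
    return sps.chi2.sf(chi2, df=1)


class TestTwoProportionZ:
    def test_equal_proportions_p_one(self):
        res = two_proportion_z_test(5, 50, 10, 100, tails="two", continuity=False)
        assert res.p_value == pytest.approx(1.0)
        assert res.statistic == pytest.approx(0.0)

    def test_matches_chi2_oracle_grid(self):
        """z^2 equals the Yates chi-square on a 100-case random grid, with
        and without correction, to 1e-10 in p."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            n1, n2 = int(rng.integers(5, 200)), int(rng.integers(5, 200))
            x1, x2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            if x1 + x2 == 0 or x1 + x2 == n1 + n2:
                continue  # degenerate table: chi-square undefined
            for corr in (True, False):
                ours = two_proportion_z_test(x1, n1, x2, n2, "two", continuity=corr)
                assert ours.p_value == pytest.approx(
                    yates_chi2_oracle(x1, n1, x2, n2, corr), abs=1e-10
                )

    def test_matches_scipy_contingency(self):
        res = two_proportion_z_test(10, 100, 30, 100, tails="two", continuity=True)
        chi2, p, _, _ = sps.chi2_contingency(
            np.array([[10, 90], [30, 70]]), correction=True
        )
        assert res.p_value == pytest.approx(p, abs=1e-12)
        assert res.statistic**2 == pytest.approx(chi2, abs=1e-10)

    def test_extreme_difference_small_p(self):
        res = two_proportion_z_test(0, 10, 10, 10, tails="two", continuity=True)
        assert res.p_value < 1e-4

    def test_one_tailed_halves_correct_tail(self):
        two = two_proportion_z_test(30, 100, 10, 100, "two", continuity=False)
        greater = two_proportion_z_test(30, 100, 10, 100, "greater", continuity=False)
        less = two_proportion_z_test(30, 100, 10, 100, "less", continuity=False)
        assert greater.p_value == pytest.approx(two.p_value / 2)
        assert less.p_value == pytest.approx(1 - two.p_value / 2)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            two_proportion_z_test(5, 0, 1, 10)
        with pytest.raises(ValueError):
            two_proportion_z_test(11, 10, 1, 10)


class TestMannWhitney:
    def test_disjoint_small_samples_exact(self):
        """{1,2,3} vs {4,5,6}: only 1 of the 20 assignments is as extreme,
        so the one-tailed exact p is 0.05."""
        res = mann_whitney_test([1, 2, 3], [4, 5, 6], tails="less")
        assert res.p_value == pytest.approx(1 / 20)
        assert "exact" in res.method

    def test_identical_samples_p_one(self):
        res = mann_whitney_test([3, 3, 3], [3, 3, 3], tails="two")
        assert res.p_value == pytest.approx(1.0)

    def test_exact_matches_scipy_all_partitions(self):
        """Exact mode agrees with scipy's exact Mann-Whitney for every
        3+4 partition of seven distinct values."""
        values = [1.0, 2.5, 3.1, 4.7, 5.2, 6.9, 8.0]
        for idx in itertools.combinations(range(7), 3):
            a = [values[i] for i in idx]
            b = [values[i] for i in range(7) if i not in idx]
            for tails, alt in (("two", "two-sided"), ("greater", "greater"), ("less", "less")):
                ours = mann_whitney_test(a, b, tails=tails)
                ref = sps.mannwhitneyu(a, b, alternative=alt, method="exact")
                assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)
                assert ours.statistic == pytest.approx(ref.statistic)

    def test_approximation_within_half_percent_of_enumeration(self):
        """For large tie-free samples (18 per group) the normal
        approximation is within 0.005 of the exact null enumeration,
        computed by an independent counting recursion over all rank
        assignments."""
        from functools import lru_cache

        n1 = n2 = 18

        @lru_cache(maxsize=None)
        def count(a, b, u):
            # number of rank assignments of a+b items giving U statistic u
            if u < 0:
                return 0
            if a == 0 or b == 0:
                return 1 if u == 0 else 0
            return count(a - 1, b, u - b) + count(a, b - 1, u)

        pmf = np.array([count(n1, n2, u) for u in range(n1 * n2 + 1)], dtype=float)
        pmf /= pmf.sum()
        cdf = np.cumsum(pmf)

        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.normal(size=n1)
            b = rng.normal(loc=rng.uniform(0, 1), size=n2)
            res = mann_whitney_test(a, b, tails="two")
            assert "approximation" in res.method
            u = int(res.statistic)
            p_le = cdf[u]
            p_ge = 1 - (cdf[u - 1] if u > 0 else 0.0)
            p_exact = min(1.0, 2 * min(p_le, p_ge))
            assert res.p_value == pytest.approx(p_exact, abs=0.005)

    def test_large_samples_use_approximation(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(loc=1.0, size=30)
        res = mann_whitney_test(a, b, tails="greater")
        ref = sps.mannwhitneyu(a, b, alternative="greater", method="asymptotic")
        assert "approximation" in res.method
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_test([], [1.0])


class TestCoefficientOfExchange:
    def test_no_calls_all_zero(self, toy_map):
        table = coefficient_of_exchange({}, toy_map, n_events=50)
        assert (table["exchange_per_meiosis"] == 0).all()

    def test_detection_correction_factor(self, toy_map):
        """5 crossovers in one bin among 100 normally segregating events
        -> 0.10 exchanges per meiosis after the x2 single-chromatid
        correction."""
        mids = {"L": np.full(5, 2_500_000)}
        table = coefficient_of_exchange(mids, toy_map, n_events=100, event_class="NORMAL")
        row = table[(table["arm"] == "L") & (table["bin_start"] == 2_000_000)].iloc[0]
        assert row["exchange_per_meiosis"] == pytest.approx(0.10)
        # MII males carry both chromatids of one homolog: no correction
        table = coefficient_of_exchange(mids, toy_map, n_events=100, event_class="MII")
        row = table[(table["arm"] == "L") & (table["bin_start"] == 2_000_000)].iloc[0]
        assert row["exchange_per_meiosis"] == pytest.approx(0.05)

    def test_conservation(self, toy_map, rng):
        mids = {"L": rng.integers(0, 8_000_000, size=40),
                "R": rng.integers(3_000_000, 12_000_000, size=25)}
        table = coefficient_of_exchange(mids, toy_map, n_events=80, event_class="MI")
        total = table["exchange_per_meiosis"].sum()
        assert total == pytest.approx(65 / 80 * 2)

    def test_flat_profile_for_uniform_density(self, toy_map, rng):
        mids = {"L": rng.integers(0, 8_000_000, size=2000)}
        table = coefficient_of_exchange(mids, toy_map, n_events=4000, event_class="MI")
        eu = table[(table["arm"] == "L") & (table["bin_end"] <= 8_000_000)]
        counts = eu["n_cos"].to_numpy()
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert sps.chi2.sf(chi2, df=len(counts) - 1) > 0.01


class TestCrossChromosome:
    def _events(self, shift=0.0, n=30, seed=3):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            k = i % 3
            rows.append(
                {"event_class": "MI", "chr2_n_co": k,
                 "other_mean_co": rng.normal(loc=shift * k, scale=0.3)}
            )
        return pd.DataFrame(rows)

    def test_identical_strata_p_one(self):
        df = pd.DataFrame(
            {"event_class": ["MI"] * 6, "chr2_n_co": [0, 1, 0, 1, 0, 1],
             "other_mean_co": [1.0, 1.0, 1.0, 1.0, 1.0, 1.0]}
        )
        out = cross_chromosome_co_comparison(df, tails={(1, 0): "two"})
        assert out["1_vs_0"].p_value == pytest.approx(1.0)

    def test_shifted_strata_small_p_right_direction(self):
        out = cross_chromosome_co_comparison(self._events(shift=2.0, n=45))
        assert out["2_vs_0"].p_value < 0.01
        assert out["2_vs_1"].p_value < 0.05

    def test_mii_events_excluded_by_default(self):
        df = self._events(n=9)
        df.loc[df.index[:6], "event_class"] = "MII"
        out = cross_chromosome_co_comparison(df)
        # only 3 MI events remain, one per stratum of size 1
        assert all(
            getattr(r, "n", None) == (1, 1) for r in out.values() if not isinstance(r, str)
        )

    def test_empty_stratum_skipped_with_notice(self):
        df = self._events(n=4)
        df["chr2_n_co"] = [0, 0, 1, 1]
        out = cross_chromosome_co_comparison(df)
        assert out["2_vs_0"] == "skipped: empty stratum"
        assert out["2_vs_1"] == "skipped: empty stratum"
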