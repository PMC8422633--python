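"""Williams-corrected G tests, rate ratios, and group contrasts."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from circalam.stats import compare_onset, compare_periods, rate_ratio_nightly, williams_g_test


def naive_williams_g(table):
    """Independent evaluation of the G statistic and Williams factor."""
    table = [list(map(float, row)) for row in table]
    r = [sum(row) for row in table]
    c = [sum(col) for col in zip(*table)]
    n = sum(r)
    g = 0.0
    for i, row in enumerate(table):
        for j, o in enumerate(row):
            e = r[i] * c[j] / n
            if o > 0:
                g += 2.0 * o * math.log(o / e)
    df = (len(r) - 1) * (len(c) - 1)
    q = 1.0 + (n * sum(1.0 / x for x in r) - 1.0) * (n * sum(1.0 / x for x in c) - 1.0) / (6.0 * n * df)
    return g, q, g / q


class TestWilliamsG:
    def test_rhythmicity_by_regimen_2x2(self):
        """LD 112/4 vs DD 51/8 rhythmic/arrhythmic gives G = 5.57, df = 1."""
        res = williams_g_test([[112, 4], [51, 8]])
        assert res.df == 1
        assert res.g == pytest.approx(5.57, abs=0.02)
        assert res.p_value == pytest.approx(0.018, abs=0.005)

    def test_independent_table_gives_zero(self):
        res = williams_g_test([[10, 10], [10, 10]])
        assert res.g == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_diagonal_table_hand_values(self):
        res = williams_g_test([[10, 0], [0, 10]])
        assert res.g_uncorrected == pytest.approx(40 * math.log(2), abs=1e-9)
        assert res.q == pytest.approx(1.075, abs=1e-3)
        assert res.g == pytest.approx(40 * math.log(2) / res.q, abs=1e-9)
        assert res.g == pytest.approx(25.79, abs=0.01)

    def test_matches_naive_oracle_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            shape = rng.integers(2, 5, size=2)
            table = rng.integers(1, 40, size=shape)
            res = williams_g_test(table)
            g, q, g_adj = naive_williams_g(table)
            assert res.g_uncorrected == pytest.approx(g, abs=1e-9)
            assert res.q == pytest.approx(q, abs=1e-12)
            assert res.g == pytest.approx(g_adj, abs=1e-9)

    def test_invariant_under_row_and_column_permutation(self):
        rng = np.random.default_rng(9)
        table = rng.integers(1, 30, size=(3, 4))
        base = williams_g_test(table).g
        assert williams_g_test(table[::-1]).g == pytest.approx(base, abs=1e-9)
        assert williams_g_test(table[:, ::-1]).g == pytest.approx(base, abs=1e-9)

    def test_correction_vanishes_with_sample_size(self):
        small = williams_g_test([[8, 4], [3, 9]])
        big = williams_g_test([[800, 400], [300, 900]])
        assert small.q > big.q > 1.0
        assert big.q == pytest.approx(1.0, abs=1e-2)

    def test_zero_marginal_is_error(self):
        with pytest.raises(ValueError, match="marginal"):
            williams_g_test([[0, 0], [5, 5]])


class TestRateRatio:
    def _draw(self, rng, rate, n_ind, n_bins=180):
        return [rng.poisson(rate, n_bins) for _ in range(n_ind)]

    def test_identical_groups_give_rr_one_ci_covering_one(self):
        rng = np.random.default_rng(10)
        a = self._draw(rng, 2.0, 20)
        b = self._draw(rng, 2.0, 20)
        res = rate_ratio_nightly(a, b, n_boot=400, seed=0)
        assert res.estimate == pytest.approx(1.0, abs=0.12)
        assert res.ci_low < 1.0 < res.ci_high

    def test_two_to_one_rates_recovered(self):
        rng = np.random.default_rng(11)
        a = self._draw(rng, 4.0, 30)
        b = self._draw(rng, 2.0, 30)
        res = rate_ratio_nightly(a, b, n_boot=400, seed=1)
        assert 1.8 <= res.estimate <= 2.2

    def test_scale_invariance_of_rr(self):
        rng = np.random.default_rng(12)
        a = self._draw(rng, 3.0, 25)
        b = self._draw(rng, 1.5, 25)
        r1 = rate_ratio_nightly(a, b, n_boot=200, seed=2)
        r2 = rate_ratio_nightly([5 * x for x in a], [5 * x for x in b], n_boot=200, seed=2)
        assert r2.estimate == pytest.approx(r1.estimate, rel=0.15)

    def test_all_zero_group_is_error(self):
        a = [np.zeros(50, dtype=int)] * 3
        b = [np.ones(50, dtype=int)] * 3
        with pytest.raises(ValueError, match="all-zero"):
            rate_ratio_nightly(a, b, n_boot=50, seed=0)

    def test_requires_two_individuals_per_group(self):
        with pytest.raises(ValueError, match=">= 2"):
            rate_ratio_nightly([np.ones(10)], [np.ones(10), np.ones(10)], n_boot=50)


class TestComparePeriods:
    def _frame(self, means, n=15, sd=0.2, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for (meal, insem), mu in means.items():
            for _ in range(n):
                rows.append({"meal": meal, "insemination": insem, "tau_h": rng.normal(mu, sd)})
        return pd.DataFrame(rows)

    def test_equal_means_give_no_rejections(self):
        means = {(m, i): 23.0 for m, i in itertools.product(("glucose", "blood"), ("virgin", "inseminated"))}
        results = compare_periods(self._frame(means, seed=1))
        assert len(results) == 6
        for r in results:
            assert abs(r.estimate) < 0.2
            assert r.p_value > 0.05

    def test_shifted_group_recovered(self):
        means = {("glucose", "virgin"): 23.0, ("glucose", "inseminated"): 23.0, ("blood", "virgin"): 23.3, ("blood", "inseminated"): 23.0}
        results = compare_periods(self._frame(means, seed=2))
        shifted = [r for r in results if "blood virgin" in r.contrast]
        assert len(shifted) == 3
        for r in shifted:
            assert abs(abs(r.estimate) - 0.3) < 0.15

    def test_two_groups_md_equals_difference_of_sample_means(self):
        df = pd.DataFrame(
            {"meal": ["glucose"] * 4 + ["blood"] * 4, "insemination": ["virgin"] * 8, "tau_h": [22.8, 23.0, 23.1, 23.3, 23.4, 23.5, 23.6, 23.9]}
        )
        (res,) = compare_periods(df)
        expected = df[df["meal"] == "blood"]["tau_h"].mean() - df[df["meal"] == "glucose"]["tau_h"].mean()
        assert res.estimate == pytest.approx(expected, abs=1e-12)

    def test_single_value_group_is_error(self):
        df = pd.DataFrame({"meal": ["glucose", "glucose", "blood"], "insemination": ["virgin"] * 3, "tau_h": [23.0, 23.1, 22.9]})
        with pytest.raises(ValueError, match="< 2"):
            compare_periods(df)


class TestCompareOnset:
    def _frame(self, delays, n=20, days=5, sd_min=2.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for group, delay in delays.items():
            for i in range(n):
                for d in range(days):
                    rows.append(
                        {"individual_id": f"{group}{i}", "group": group, "onset_clock_h": 18.0 + (delay + rng.normal(0, sd_min)) / 60.0}
                    )
        return pd.DataFrame(rows)

    def test_identical_distributions_give_near_zero_delay(self):
        (res,) = compare_onset(self._frame({"a": 0.0, "b": 0.0}, seed=3), n_boot=400, seed=4)
        assert abs(res.estimate) < 1.0
        assert res.ci_low < 0.0 < res.ci_high

    def test_injected_four_minute_delay_recovered(self):
        (res,) = compare_onset(self._frame({"a": 4.0, "b": 0.0}, seed=5), n_boot=400, seed=6)
        assert res.estimate == pytest.approx(4.0, abs=1.0)
        assert res.p_value < 0.05

    def test_missing_days_ignored_in_individual_means(self):
        df = self._frame({"a": 2.0, "b": 0.0}, n=5, seed=7)
        df.loc[df.sample(frac=0.3, random_state=0).index, "onset_clock_h"] = np.nan
        (res,) = compare_onset(df, n_boot=200, seed=8)
        assert np.isfinite(res.estimate)

    def test_group_without_onsets_is_error(self):
        df = self._frame({"a": 0.0, "b": 0.0}, n=3, seed=9)
        df.loc[df["group"] == "b", "onset_clock_h"] = np.nan
        with pytest.raises(ValueError, match="< 2 individuals"):
            compare_onset(df, n_boot=50)
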