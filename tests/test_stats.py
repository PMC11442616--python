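"""Signed-rank / rank-sum tests against brute-force enumeration and scipy,
descriptives against a sort-based oracle, OLS, and control matching."""

import itertools
from dataclasses import dataclass

import numpy as np
import pytest
from scipy import stats as sps

from dtialps.stats import (describe, linear_regression, mann_whitney_u,
                           match_controls, wilcoxon_signed_rank)


def brute_force_signrank_p(d):
    """Independent oracle: enumerate all 2^n sign assignments explicitly."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    total = ranks.sum()
    w_min = min(w_plus, total - w_plus)
    count = 0
    n = len(d)
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, bool)].sum()
        if w <= w_min + 1e-9 or w >= total - w_min - 1e-9:
            count += 1
    return min(1.0, count / 2**n)


def brute_force_ranksum_p(a, b):
    """Independent oracle: enumerate all C(N, n_a) group labelings."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    u_min = min(u_obs, n_a * len(b) - u_obs)
    count = total = 0
    for subset in itertools.combinations(range(len(pooled)), n_a):
        u = ranks[list(subset)].sum() - n_a * (n_a + 1) / 2
        total += 1
        if u <= u_min + 1e-9 or u >= n_a * len(b) - u_min - 1e-9:
            count += 1
    return min(1.0, count / total)


class TestWilcoxonSignedRank:
    def test_exact_p_matches_sign_enumeration(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 0.0])
        y = np.array([0.0, 0.0, 0.0, 0.0, 5.0])  # d = (+1, +2, +3, +4, -5)
        res = wilcoxon_signed_rank(x, y)
        assert res.method.endswith("(exact)")
        assert res.p_two_sided == pytest.approx(brute_force_signrank_p(x - y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_enumeration_on_random_data_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        d = rng.integers(-5, 6, n).astype(float)
        d[d == 0] = 1.0
        res = wilcoxon_signed_rank(d, np.zeros(n))
        assert res.p_two_sided == pytest.approx(brute_force_signrank_p(d), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_scipy_without_ties(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.standard_normal(12)
        y = rng.standard_normal(12)
        ours = wilcoxon_signed_rank(x, y)
        ref = sps.wilcoxon(x, y, method="exact")
        assert ours.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    def test_approximation_matches_scipy_tie_corrected(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 8, 30).astype(float)
        y = rng.integers(0, 8, 30).astype(float)
        keep = x != y
        ours = wilcoxon_signed_rank(x[keep], y[keep])
        ref = sps.wilcoxon(x[keep], y[keep], zero_method="wilcox",
                           correction=True, method="approx")
        assert ours.method.endswith("(normal-approximation)")
        assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-10)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="no effective pairs"):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_symmetric_in_argument_order(self, rng):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        assert (wilcoxon_signed_rank(x, y).p_two_sided
                == pytest.approx(wilcoxon_signed_rank(y, x).p_two_sided, abs=1e-14))

    def test_exact_null_distribution_sums_to_one(self):
        # the DP-enumerated null over all sign assignments is a probability mass
        from dtialps.stats import _signflip_exact_p

        ranks = sps.rankdata([1, 2, 2, 4, 5, 5, 5, 8])
        # p at the distribution maximum must be exactly 1
        total = ranks.sum()
        assert _signflip_exact_p(ranks, total / 2) == pytest.approx(1.0)

    def test_pratt_zero_handling_keeps_zero_ranks(self):
        x = np.array([0.0, 1.0, 2.0, -4.0, 5.0])
        wil = wilcoxon_signed_rank(x, np.zeros(5), zero_method="wilcox")
        pratt = wilcoxon_signed_rank(x, np.zeros(5), zero_method="pratt")
        assert wil.n_effective == pratt.n_effective == 4
        assert wil.statistic != pratt.statistic  # zero shifts the ranks up


class TestMannWhitneyU:
    def test_identical_groups_give_central_u_and_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = mann_whitney_u(a, a.copy())  # fully tied: forced to the approximation
        assert res.statistic == pytest.approx(len(a) ** 2 / 2)
        assert res.p_two_sided == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_matches_labeling_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.permutation(20)[:4].astype(float)
        b = rng.permutation(40)[:4].astype(float) + 0.5  # guarantees no ties
        res = mann_whitney_u(a, b)
        assert res.method.endswith("(exact)")
        assert res.p_two_sided == pytest.approx(brute_force_ranksum_p(a, b), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_scipy(self, seed):
        rng = np.random.default_rng(200 + seed)
        a = rng.standard_normal(6)
        b = rng.standard_normal(6)
        ours = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, method="exact")
        assert ours.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    def test_approximation_matches_scipy_tie_corrected(self):
        rng = np.random.default_rng(9)
        a = rng.integers(0, 6, 15).astype(float)
        b = rng.integers(0, 6, 12).astype(float)
        ours = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, method="asymptotic", use_continuity=True)
        assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-10)

    def test_u_statistics_sum_to_product_of_sizes(self, rng):
        a = rng.standard_normal(9)
        b = rng.standard_normal(13)
        ranks = sps.rankdata(np.concatenate([a, b]))
        u_a = ranks[:9].sum() - 9 * 10 / 2
        u_b = ranks[9:].sum() - 13 * 14 / 2
        assert u_a + u_b == pytest.approx(9 * 13)
        assert mann_whitney_u(a, b).statistic == pytest.approx(min(u_a, u_b))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0, 2.0])


class TestLinearRegression:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        res = linear_regression(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_r_squared_invariant_under_standardization(self, rng):
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        r2 = linear_regression(x, y).r_squared
        zx = (x - x.mean()) / x.std(ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        assert linear_regression(zx, zy).r_squared == pytest.approx(r2, abs=1e-12)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant predictor"):
            linear_regression(np.ones(5), np.arange(5.0))

    def test_slope_p_matches_statsmodels_style_t_test(self, rng):
        x = rng.standard_normal(25)
        y = 0.3 * x + rng.standard_normal(25)
        res = linear_regression(x, y)
        # independent route: t statistic from the correlation coefficient
        r = np.corrcoef(x, y)[0, 1]
        t = r * np.sqrt(23 / (1 - r**2))
        assert res.p_slope == pytest.approx(2 * sps.t.sf(abs(t), 23), rel=1e-10)


class TestDescribe:
    def test_constant_sample(self):
        d = describe([1.0, 1.0, 1.0])
        assert d.sd == 0.0 and d.median == 1.0

    def test_median_and_hinges_match_sort_based_oracle(self, rng):
        for n in (4, 5, 10, 11, 24):
            v = rng.standard_normal(n)
            d = describe(v)
            s = np.sort(v)
            med = (s[n // 2 - 1] + s[n // 2]) / 2 if n % 2 == 0 else s[n // 2]
            lower, upper = s[: n // 2], s[-(n // 2):]

            def half_med(h):
                m = len(h)
                return (h[m // 2 - 1] + h[m // 2]) / 2 if m % 2 == 0 else h[m // 2]

            assert d.median == pytest.approx(med)
            assert d.q1 == pytest.approx(half_med(lower))
            assert d.q3 == pytest.approx(half_med(upper))
            assert d.q1 <= d.median <= d.q3

    def test_population_sd_option(self):
        v = [1.0, 2.0, 3.0, 4.0]
        assert describe(v, ddof=0).sd == pytest.approx(np.std(v))
        assert describe(v).sd == pytest.approx(np.std(v, ddof=1))

    def test_single_value_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            describe([1.0])


@dataclass(frozen=True)
class Subject:
    id: int
    age: float
    sex: str


class TestMatchControls:
    def test_same_sex_within_two_years_is_eligible(self):
        patients = [Subject(27, 32, "male")]
        controls = [Subject(1, 33, "male")]
        assignment = match_controls(patients, controls)
        assert assignment.pairs == ((27, 1),)

    def test_empty_control_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            match_controls([Subject(1, 50, "male")], [])

    def test_out_of_tolerance_patient_reported(self):
        with pytest.raises(ValueError, match="no control within"):
            match_controls([Subject(1, 50, "male")], [Subject(1, 60, "male")])

    def test_controls_may_serve_several_patients(self):
        patients = [Subject(i, 50 + i % 2, "female") for i in range(1, 5)]
        controls = [Subject(1, 50, "female")]
        assignment = match_controls(patients, controls)
        assert all(cid == 1 for _, cid in assignment.pairs)

    def test_greedy_agrees_with_exhaustive_on_small_cohort(self):
        patients = [Subject(1, 30, "male"), Subject(2, 40, "female"), Subject(3, 52, "male")]
        controls = [Subject(1, 31, "male"), Subject(2, 39, "female"),
                    Subject(3, 51, "male"), Subject(4, 41, "female")]
        greedy = dict(match_controls(patients, controls).pairs)
        # exhaustive oracle: per patient, minimal |age gap| then lowest id
        for p in patients:
            candidates = [(abs(c.age - p.age), c.id) for c in controls
                          if c.sex == p.sex and abs(c.age - p.age) <= 2]
            assert greedy[p.id] == min(candidates)[1]

    def test_table_fixture_mapping_is_age_sex_consistent(self, patients, controls):
        # the source table itself stretches its +/- 2 years for two pairs
        # (patient 7 vs control 5 and patient 16 vs control 3: 3-year gaps)
        known_stretched = {7, 16}
        by_id = {p.id: p for p in patients}
        for c in controls:
            for pid in c.matched_patient_ids:
                p = by_id[pid]
                assert p.sex == c.sex
                assert abs(p.age - c.age) <= (3 if pid in known_stretched else 2)
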