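"""Nonparametric paired/two-sample tests, descriptives, OLS and matching.

The signed-rank and rank-sum tests are implemented here rather than taken
from scipy because the required variant mix — exact enumeration over the
null with midranks for ties at small n, tie-corrected continuity-corrected
normal approximation otherwise — is not available as a single scipy
configuration (scipy's exact methods refuse ties and zeros).  The exact
paths are validated against brute-force enumeration and scipy in the test
suite.

Conventions:

* signed rank: zero differences are discarded before ranking (Wilcoxon's
  original treatment, the default of the common commercial toolboxes);
  the Pratt variant (rank with zeros, then drop them) is available via
  ``zero_method="pratt"``.
* two-sided p-values throughout; significance level of the study is 0.05.
* with midranks, the sign-flip variance sum(r_i^2)/4 equals the
  tie-corrected variance n(n+1)(2n+1)/24 - sum(t^3 - t)/48, so one formula
  covers the tied, untied and Pratt cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "Descriptives",
    "RegressionResult",
    "MatchAssignment",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "linear_regression",
    "describe",
    "match_controls",
]

EXACT_SIGNRANK_MAX_N = 15
EXACT_RANKSUM_MAX_TOTAL = 12


@dataclass(frozen=True)
class TestResult:
    method: str  # e.g. "wilcoxon-signed-rank (exact)"
    statistic: float
    p_two_sided: float
    n_effective: int

    def __post_init__(self):
        if not 0.0 <= self.p_two_sided <= 1.0:
            raise ValueError(f"p-value {self.p_two_sided} outside [0, 1]")


@dataclass(frozen=True)
class Descriptives:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n: int


@dataclass(frozen=True)
class MatchAssignment:
    pairs: tuple  # of (patient_id, control_id)
    tolerance_years: float
    hemisphere_rule: str


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _signflip_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p of the sign-flip null by dynamic programming.

    Enumerates the distribution of W+ over all 2^n sign assignments using
    a polynomial product over doubled ranks (midranks are multiples of
    1/2, so doubling gives integer support).
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = 2.0 * w_plus
    w_min2 = min(w2, total - w2)
    support = np.arange(total + 1)
    # half-rank support is integer, so a 1e-9 slack only absorbs rounding
    p = counts[support <= w_min2 + 1e-9].sum() + counts[support >= total - w_min2 - 1e-9].sum()
    return float(min(1.0, p))


def wilcoxon_signed_rank(x, y, zero_method: str = "wilcox", mode: str = "auto",
                         continuity: bool = True) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Differences ``d = x - y``; zeros are discarded (``zero_method="wilcox"``)
    or ranked-then-dropped (``"pratt"``); |d| is ranked with midranks.  The
    reported statistic is ``W = min(W+, W-)``.  Exact enumeration of all
    sign assignments is used when the number of effective pairs is <= 15
    (or ``mode="exact"``); otherwise a normal approximation with
    tie-corrected variance and, unless ``continuity=False``, a 0.5
    continuity correction (some toolboxes omit it; the flag allows
    matching either convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D paired samples of equal length")
    if len(x) < 1:
        raise ValueError("need at least one pair")
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")
    d = x - y
    nonzero = d != 0
    if not np.any(nonzero):
        raise ValueError("no effective pairs: all differences are zero")
    if zero_method == "wilcox":
        d_eff = d[nonzero]
        ranks = _midranks(np.abs(d_eff))
    else:
        ranks_all = _midranks(np.abs(d))
        d_eff = d[nonzero]
        ranks = ranks_all[nonzero]
    n_eff = int(nonzero.sum())
    w_plus = float(ranks[d_eff > 0].sum())
    w_minus = float(ranks.sum() - w_plus)
    statistic = min(w_plus, w_minus)

    exact = mode == "exact" or (mode == "auto" and n_eff <= EXACT_SIGNRANK_MAX_N)
    if exact:
        p = _signflip_exact_p(ranks, w_plus)
        method = "wilcoxon-signed-rank (exact)"
    else:
        mean = ranks.sum() / 2.0
        var = float(np.sum(ranks**2)) / 4.0
        if var == 0:
            raise ValueError("zero variance: degenerate ranking")
        cc = 0.5 if continuity else 0.0
        z = (w_plus - mean - cc * np.sign(w_plus - mean)) / math.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        method = "wilcoxon-signed-rank (normal-approximation)"
    return TestResult(method=method, statistic=statistic, p_two_sided=p, n_effective=n_eff)


def mann_whitney_u(a, b, mode: str = "auto", continuity: bool = True) -> TestResult:
    """Two-sided Mann-Whitney U test on independent samples.

    U is computed from midranks; the reported statistic is
    ``min(U_a, U_b)``.  Exact enumeration over all C(N, n_a) labelings is
    used when N = n_a + n_b <= 12 and there are no ties; otherwise the
    normal approximation with tie-corrected variance and a 0.5 continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty 1D samples")
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    r_a = float(ranks[:n_a].sum())
    u_a = r_a - n_a * (n_a + 1) / 2.0
    u_b = n_a * n_b - u_a
    statistic = min(u_a, u_b)
    has_ties = len(np.unique(pooled)) < len(pooled)

    exact = mode == "exact" or (
        mode == "auto" and n_a + n_b <= EXACT_RANKSUM_MAX_TOTAL and not has_ties
    )
    if exact:
        if has_ties:
            raise ValueError("exact rank-sum p is only defined without ties")
        n = n_a + n_b
        all_ranks = np.arange(1, n + 1)
        u_min = min(u_a, u_b)
        count_extreme = 0
        total = 0
        offset = n_a * (n_a + 1) / 2.0
        for comb in combinations(all_ranks, n_a):
            u = sum(comb) - offset
            total += 1
            if u <= u_min + 1e-9 or u >= n_a * n_b - u_min - 1e-9:
                count_extreme += 1
        p = min(1.0, count_extreme / total)
        method = "mann-whitney-u (exact)"
    else:
        n = n_a + n_b
        mean = n_a * n_b / 2.0
        # tie-corrected variance of U via the general midrank form
        var = n_a * n_b / (n * (n - 1.0)) * (float(np.sum(ranks**2)) - n * (n + 1.0) ** 2 / 4.0)
        if var == 0:
            raise ValueError("zero variance: all pooled values identical")
        cc = 0.5 if continuity else 0.0
        z = (u_a - mean - cc * np.sign(u_a - mean)) / math.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        method = "mann-whitney-u (normal-approximation)"
    return TestResult(method=method, statistic=statistic, p_two_sided=float(p),
                      n_effective=n_a + n_b)


def linear_regression(x, y) -> RegressionResult:
    """Simple OLS of y on x with the two-sided slope t-test (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3 for the slope test")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: slope undefined")
    res = sps.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=float(res.rvalue**2), p_slope=float(res.pvalue),
                            n=len(x))


def _half_median(sorted_vals: np.ndarray) -> float:
    n = len(sorted_vals)
    mid = n // 2
    if n % 2:
        return float(sorted_vals[mid])
    return float((sorted_vals[mid - 1] + sorted_vals[mid]) / 2.0)


def describe(v, ddof: int = 1) -> Descriptives:
    """n, mean, sample sd, median and quartiles of one sample.

    Quartiles use the midpoint-of-halves convention with the median
    excluded for odd n (Moore-McCabe hinges): Q1 is the median of the lower
    half, Q3 of the upper half.  ``ddof=0`` gives the population-style sd
    some reports print.
    """
    v = np.sort(np.asarray(v, dtype=float))
    n = len(v)
    if n < 2:
        raise ValueError("need n >= 2 for the sample standard deviation")
    lower = v[: n // 2]
    upper = v[-(n // 2):]
    return Descriptives(
        n=n,
        mean=float(v.mean()),
        sd=float(v.std(ddof=ddof)),
        median=_half_median(v),
        q1=_half_median(lower),
        q3=_half_median(upper),
    )


def match_controls(patients, controls, tolerance_years: float = 2.0,
                   hemisphere_rule: str = "tumor_side") -> MatchAssignment:
    """Greedy nearest-age same-sex assignment of controls to patients.

    ``patients`` and ``controls`` are sequences of objects with ``id``,
    ``age`` and ``sex`` attributes.  A control may serve several patients.
    ``hemisphere_rule`` (one of ``tumor_side``, ``fixed_left``,
    ``fixed_right``) records which control hemisphere downstream
    comparisons should read; it does not influence the pairing.
    """
    if hemisphere_rule not in ("tumor_side", "fixed_left", "fixed_right"):
        raise ValueError(f"unknown hemisphere_rule {hemisphere_rule!r}")
    patients = list(patients)
    controls = list(controls)
    if not patients or not controls:
        raise ValueError("patients and controls must both be non-empty")
    pairs = []
    for p in patients:
        eligible = [c for c in controls
                    if c.sex == p.sex and abs(c.age - p.age) <= tolerance_years]
        if not eligible:
            raise ValueError(
                f"patient {p.id} ({p.sex}, {p.age}y) has no control within "
                f"{tolerance_years} years"
            )
        best = min(eligible, key=lambda c: (abs(c.age - p.age), c.id))
        pairs.append((p.id, best.id))
    return MatchAssignment(pairs=tuple(pairs), tolerance_years=tolerance_years,
                           hemisphere_rule=hemisphere_rule)
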