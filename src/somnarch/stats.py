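"""Small-sample group statistics: Mann-Whitney U, rank effect size, CIs,
bootstrap differences, ICC and the Friedman test.

The asymptotic Mann-Whitney p uses the normal approximation

    z = (U - n1 n2 / 2) / sqrt(n1 n2 (N + 1) / 12)

with midranks and tie-corrected variance but no continuity correction,
matching common clinical-statistics software output for small groups.  The
exact p enumerates every C(N, n1) group assignment of the pooled midranks
and doubles the lower tail.  The rank-based effect size converts the same
z to r = z / sqrt(N) and then to a Cohen's-d-scale value

    d = 2 r / sqrt(1 - r^2),

the standard r-to-d transform.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "mann_whitney",
    "rank_effect_size",
    "t_ci",
    "bootstrap_diff",
    "icc_absolute",
    "friedman",
    "compare_variable",
]

EXACT_ENUMERATION_LIMIT = 10**6


@dataclass
class GroupComparison:
    """Two-group comparison of one variable, Table-style."""

    variable: str
    n1: int
    n2: int
    mean1: float
    sd1: float
    ci1: tuple[float, float] | None
    mean2: float
    sd2: float
    ci2: tuple[float, float] | None
    U: float
    p_asymptotic: float
    p_exact: float | None
    effect_d: float
    p_boot: float | None = None
    ci_boot: tuple[float, float] | None = None

    def as_dict(self) -> dict:
        return {
            "variable": self.variable,
            "n1": self.n1,
            "n2": self.n2,
            "mean1": self.mean1,
            "sd1": self.sd1,
            "ci1_lo": self.ci1[0] if self.ci1 else None,
            "ci1_hi": self.ci1[1] if self.ci1 else None,
            "mean2": self.mean2,
            "sd2": self.sd2,
            "ci2_lo": self.ci2[0] if self.ci2 else None,
            "ci2_hi": self.ci2[1] if self.ci2 else None,
            "U": self.U,
            "p_asymptotic": self.p_asymptotic,
            "p_exact": self.p_exact,
            "effect_d": self.effect_d,
            "p_boot": self.p_boot,
            "ci_boot_lo": self.ci_boot[0] if self.ci_boot else None,
            "ci_boot_hi": self.ci_boot[1] if self.ci_boot else None,
        }


def _mwu_z(U: float, n1: int, n2: int, tie_term: float = 0.0) -> float:
    """Normal-approximation z for U (tie-corrected variance, no continuity)."""
    N = n1 + n2
    mu = n1 * n2 / 2.0
    var = n1 * n2 * (N + 1) / 12.0 - tie_term
    if var <= 0:
        return 0.0
    return (U - mu) / np.sqrt(var)


def _tie_term(pooled: np.ndarray, n1: int, n2: int) -> float:
    N = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    t = counts[counts > 1]
    if t.size == 0:
        return 0.0
    return n1 * n2 * ((t**3 - t).sum()) / (12.0 * N * (N - 1))


def mann_whitney(xs, ys, exact: bool = True) -> tuple[float, float, float | None]:
    """Mann-Whitney U with asymptotic and (when feasible) exact p.

    Returns ``(U, p_asymptotic, p_exact)`` where U = min(U1, U2) from
    midrank sums.  ``p_exact`` enumerates all C(N, n1) assignments of the
    pooled midranks, counting those whose min-tail U is at or below the
    observed one (None when ``exact=False`` or beyond 10^6 combinations).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = xs.size, ys.size
    pooled = np.concatenate([xs, ys])
    ranks = sps.rankdata(pooled)  # midranks
    r1 = ranks[:n1].sum()
    U1 = r1 - n1 * (n1 + 1) / 2.0
    U2 = n1 * n2 - U1
    U = min(U1, U2)
    z = _mwu_z(U1, n1, n2, _tie_term(pooled, n1, n2))
    p_asym = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))

    p_exact = None
    n_comb = comb(n1 + n2, n1)
    if exact and n_comb <= EXACT_ENUMERATION_LIMIT:
        count = 0
        base = n1 * (n1 + 1) / 2.0
        for c in combinations(range(n1 + n2), n1):
            u1 = ranks[list(c)].sum() - base
            if min(u1, n1 * n2 - u1) <= U + 1e-9:
                count += 1
        p_exact = float(min(1.0, count / n_comb))
    return float(U), p_asym, p_exact


def rank_effect_size(U: float, n1: int, n2: int) -> float:
    """Rank-based Cohen's-d-scale effect size from U and the group sizes.

    z is the (untied) normal approximation; r = z / sqrt(N);
    d = 2 r / sqrt(1 - r^2).  Returns +inf when r reaches 1.
    """
    if not 0 <= U <= n1 * n2:
        raise ValueError("U outside [0, n1*n2]")
    N = n1 + n2
    z = abs(_mwu_z(U, n1, n2))
    r = z / np.sqrt(N)
    if r >= 1.0:
        return float("inf")
    return float(2.0 * r / np.sqrt(1.0 - r**2))


def t_ci(mean: float, sd: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """t-based confidence interval for a mean: mean ± t_{n-1} * sd / sqrt(n)."""
    if n < 2:
        raise ValueError("need n >= 2 for a CI")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    tcrit = sps.t.ppf(0.5 + level / 2.0, df=n - 1)
    half = tcrit * sd / np.sqrt(n)
    return (float(mean - half), float(mean + half))


def bootstrap_diff(
    xs, ys, n_boot: int = 1000, seed: int = 0
) -> tuple[float, tuple[float, float], bool]:
    """Bootstrap the group difference of means (x - y).

    Resamples each group with replacement ``n_boot`` times; returns the
    add-one-smoothed two-tailed p (fraction of the difference distribution
    at or beyond zero, doubled), the percentile 95% CI and a low-iteration
    flag (n_boot < 100).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size < 2 or ys.size < 2:
        raise ValueError("need >= 2 observations per group")
    rng = np.random.default_rng(seed)
    bx = rng.integers(0, xs.size, (n_boot, xs.size))
    by = rng.integers(0, ys.size, (n_boot, ys.size))
    diffs = xs[bx].mean(axis=1) - ys[by].mean(axis=1)
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    n_le = int((diffs <= 0).sum())
    n_ge = int((diffs >= 0).sum())
    p = 2.0 * (min(n_le, n_ge) + 1.0) / (n_boot + 1.0)
    return float(min(1.0, p)), (float(lo), float(hi)), n_boot < 100


def icc_absolute(ratings: np.ndarray) -> float:
    """ICC for absolute agreement, two-way model, single measures (ICC(A,1)).

    ``ratings`` is subjects x raters.  Computed from the two-way ANOVA mean
    squares:

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)

    Returns NaN for degenerate (constant) tables.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need >= 3 subjects and >= 2 raters")
    n, k = x.shape
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ss_rows = k * ((row_m - grand) ** 2).sum()
    ss_cols = n * ((col_m - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if denom <= 0 or np.isclose(ss_tot, 0.0):
        return float("nan")
    return float((ms_r - ms_e) / denom)


def friedman(matrix: np.ndarray) -> tuple[float, int, float]:
    """Friedman chi-square over a subjects x conditions table (midranks).

    Thin wrapper over the SciPy implementation, returning
    ``(statistic, df, p)`` with df = k - 1.  Identical columns give a
    statistic of 0.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    k = x.shape[1]
    if np.allclose(x, x[:, [0]]):
        return 0.0, k - 1, 1.0
    stat, p = sps.friedmanchisquare(*[x[:, j] for j in range(k)])
    return float(stat), k - 1, float(p)


def compare_variable(
    name: str, xs, ys, n_boot: int = 1000, seed: int = 0
) -> GroupComparison:
    """Full two-group report for one variable (means, CIs, U, d, bootstrap)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    U, p_asym, p_exact = mann_whitney(xs, ys)
    d = rank_effect_size(U, xs.size, ys.size)
    ci1 = t_ci(xs.mean(), xs.std(ddof=1), xs.size) if xs.size >= 2 else None
    ci2 = t_ci(ys.mean(), ys.std(ddof=1), ys.size) if ys.size >= 2 else None
    p_boot, ci_boot = None, None
    if xs.size >= 2 and ys.size >= 2:
        p_boot, ci_boot, _ = bootstrap_diff(xs, ys, n_boot=n_boot, seed=seed)
    return GroupComparison(
        variable=name,
        n1=int(xs.size),
        n2=int(ys.size),
        mean1=float(xs.mean()),
        sd1=float(xs.std(ddof=1)) if xs.size >= 2 else 0.0,
        ci1=ci1,
        mean2=float(ys.mean()),
        sd2=float(ys.std(ddof=1)) if ys.size >= 2 else 0.0,
        ci2=ci2,
        U=U,
        p_asymptotic=p_asym,
        p_exact=p_exact,
        effect_d=d,
        p_boot=p_boot,
        ci_boot=ci_boot,
    )
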