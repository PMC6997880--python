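"""Statistics layer: MWU (asymptotic + exact), effect size, CIs, bootstrap,
ICC and Friedman, validated against enumeration and published software output."""
import numpy as np
import pytest
from scipy import stats as sps

from somnarch.stats import (
    bootstrap_diff,
    compare_variable,
    friedman,
    icc_absolute,
    mann_whitney,
    rank_effect_size,
    t_ci,
)


# --- Mann-Whitney -----------------------------------------------------------

def test_complete_separation_exact_p():
    xs = [1, 2, 3, 4]
    ys = list(range(5, 15))
    U, p_asym, p_exact = mann_whitney(xs, ys)
    assert U == 0.0
    assert p_exact == pytest.approx(2 / 1001)


def test_u3_asymptotic_p_rounds_to_0016():
    """U = 3 with n = 4 vs 10: z = -17/sqrt(50), two-tailed p ~ 0.0163."""
    xs = [1, 2, 4, 6]
    ys = [3, 5] + list(range(7, 15))  # rank sum 13 -> U = 3, no ties
    U, p_asym, p_exact = mann_whitney(xs, ys)
    assert U == 3.0
    assert round(p_asym, 3) == 0.016
    assert p_exact == pytest.approx(14 / 1001)  # rounds to 0.014


def test_exact_p_matches_scipy_enumeration():
    """Exact two-tailed p equals the reference enumeration for all n <= 12."""
    rng = np.random.default_rng(0)
    for _ in range(60):
        n1 = int(rng.integers(1, 6))
        n2 = int(rng.integers(1, 13 - n1))
        xs = rng.normal(size=n1)
        ys = rng.normal(size=n2)  # continuous -> no ties
        _, _, p_exact = mann_whitney(xs, ys)
        ref = sps.mannwhitneyu(xs, ys, alternative="two-sided", method="exact").pvalue
        assert p_exact == pytest.approx(ref, abs=1e-12)


def test_mwu_handles_ties_with_midranks():
    xs = [1.0, 2.0, 2.0]
    ys = [2.0, 3.0, 4.0]
    U, p_asym, p_exact = mann_whitney(xs, ys)
    assert 0 <= U <= 9
    assert 0 < p_asym <= 1
    assert 0 < p_exact <= 1


def test_mwu_type_one_error_calibrated():
    """Asymptotic test at alpha=.05, n=4 vs 10: rejection rate in [0.01, 0.08]."""
    rng = np.random.default_rng(42)
    rejections = 0
    reps = 2000
    for _ in range(reps):
        xs = rng.normal(size=4)
        ys = rng.normal(size=10)
        _, p, _ = mann_whitney(xs, ys, exact=False)
        rejections += p < 0.05
    assert 0.01 <= rejections / reps <= 0.08


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


# --- effect size ------------------------------------------------------------

PRINTED_EFFECT_SIZES = {
    3.0: 1.68, 8.0: 1.02, 10.0: 0.82, 11.5: 0.68, 12.0: 0.63, 14.0: 0.47,
    15.0: 0.39, 16.5: 0.27, 17.0: 0.23, 18.0: 0.15, 19.0: 0.08,
}


@pytest.mark.parametrize("U,expected", sorted(PRINTED_EFFECT_SIZES.items()))
def test_rank_effect_size_reproduces_published_values(U, expected):
    assert rank_effect_size(U, 4, 10) == pytest.approx(expected, abs=0.01)


def test_effect_size_null_and_degenerate():
    assert rank_effect_size(20.0, 4, 10) == 0.0  # U = n1 n2 / 2
    assert rank_effect_size(0.0, 100, 100) > 3.0
    with pytest.raises(ValueError):
        rank_effect_size(50.0, 4, 10)


# --- confidence intervals ---------------------------------------------------

@pytest.mark.parametrize(
    "mean,sd,n,lo,hi",
    [(3.50, 1.00, 4, 1.91, 5.09), (4.90, 3.31, 10, 2.53, 7.27)],
)
def test_t_ci_reproduces_published_values(mean, sd, n, lo, hi):
    got = t_ci(mean, sd, n)
    assert got[0] == pytest.approx(lo, abs=0.005)
    assert got[1] == pytest.approx(hi, abs=0.005)


def test_t_ci_degenerate_cases():
    assert t_ci(5.0, 0.0, 4) == (5.0, 5.0)
    with pytest.raises(ValueError):
        t_ci(5.0, 1.0, 1)


# --- bootstrap --------------------------------------------------------------

def test_bootstrap_null_coverage():
    """CI straddles zero in >= 93% of null simulations."""
    rng = np.random.default_rng(7)
    covered = 0
    for rep in range(100):
        xs = rng.normal(size=20)
        ys = rng.normal(size=20)
        _, (lo, hi), _ = bootstrap_diff(xs, ys, n_boot=1000, seed=rep)
        covered += lo <= 0 <= hi
    assert covered >= 93


def test_bootstrap_separated_groups_exclude_zero(rng):
    ys = rng.normal(size=10)
    xs = ys[:8] + 10.0
    p, (lo, hi), low = bootstrap_diff(xs, ys, n_boot=1000, seed=0)
    assert lo > 0
    assert p < 0.01
    assert low is False


def test_bootstrap_deterministic_and_flags_low_iterations(rng):
    xs, ys = rng.normal(size=5), rng.normal(size=6)
    out1 = bootstrap_diff(xs, ys, n_boot=500, seed=3)
    out2 = bootstrap_diff(xs, ys, n_boot=500, seed=3)
    assert out1 == out2
    assert bootstrap_diff(xs, ys, n_boot=50, seed=0)[2] is True


# --- ICC --------------------------------------------------------------------

def test_icc_perfect_agreement(rng):
    x = rng.normal(size=10)
    assert icc_absolute(np.column_stack([x, x])) == pytest.approx(1.0)


def test_icc_penalises_constant_offset(rng):
    x = rng.normal(size=10)
    val = icc_absolute(np.column_stack([x, x + 5.0]))
    assert val < 0.5


def test_icc_matches_published_implementation(rng):
    pg = pytest.importorskip("pingouin")
    import pandas as pd

    x = rng.normal(loc=10, scale=2, size=12)
    y = x + rng.normal(scale=1.0, size=12)
    table = np.column_stack([x, y])
    mine = icc_absolute(table)
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile(["a", "b"], 12),
            "score": table.ravel(),
        }
    )
    ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    sel = ref["Type"].isin(["ICC(A,1)", "ICC2"])  # label differs across versions
    icc_a1 = float(ref.loc[sel, "ICC"].iloc[0])
    assert mine == pytest.approx(icc_a1, abs=1e-6)


def test_icc_degenerate_constant_table():
    assert np.isnan(icc_absolute(np.ones((5, 2))))
    with pytest.raises(ValueError):
        icc_absolute(np.ones((2, 2)))


# --- Friedman ---------------------------------------------------------------

def test_friedman_identical_columns_zero():
    x = np.tile(np.arange(5.0)[:, None], (1, 3))
    stat, df, p = friedman(x)
    assert stat == 0.0
    assert df == 2


def test_friedman_monotone_maximal():
    """Every subject ranks A<B<C: chi2 = 12n/(k(k+1)) * sum((rbar-2)^2) = 8."""
    x = np.array([[1, 2, 3]] * 4, dtype=float) + np.arange(4)[:, None]
    stat, df, p = friedman(x)
    assert stat == pytest.approx(8.0)
    assert df == 2


def test_friedman_matches_rank_formula(rng):
    x = rng.normal(size=(6, 4))
    stat, df, p = friedman(x)
    ranks = np.vstack([sps.rankdata(row) for row in x])
    n, k = x.shape
    rbar = ranks.mean(axis=0)
    chi_naive = 12 * n / (k * (k + 1)) * ((rbar - (k + 1) / 2) ** 2).sum()
    assert stat == pytest.approx(chi_naive, rel=1e-9)  # no ties in normals
    assert df == 3


# --- assembled comparison ---------------------------------------------------

def test_compare_variable_assembles_consistent_report(rng):
    xs = rng.normal(loc=0, size=4)
    ys = rng.normal(loc=3, size=10)
    rep = compare_variable("tst_min", xs, ys, n_boot=500, seed=1)
    assert 0 <= rep.U <= 40
    assert 0 <= rep.p_asymptotic <= 1
    assert rep.p_exact is not None and 0 <= rep.p_exact <= 1
    assert rep.effect_d >= 0
    assert rep.ci1[0] < rep.mean1 < rep.ci1[1]
    assert rep.ci_boot is not None
    d = rep.as_dict()
    assert d["variable"] == "tst_min"
    assert d["n1"] == 4 and d["n2"] == 10
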