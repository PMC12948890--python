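"""Repeated-measures battery: cross-checks against pingouin and scipy,
plus calibration of the combined decision procedure."""

import numpy as np
import pytest
from scipy import stats

from emct2 import analyze_block, friedman_test, normality_screen, rm_anova


def _fixture_block(n=10, seed=20250823):
    """Deterministic 10x3 block shaped like per-sample compartment means:
    baseline ~43 ms, a -2% run dip, partial recovery, correlated samples."""
    rng = np.random.default_rng(seed)
    subject = 43.0 + rng.normal(0.0, 2.5, n)
    eps = rng.normal(0.0, 0.8, (n, 3))
    block = np.column_stack([subject, subject * 0.98, subject * 0.995]) + eps
    return block


def test_null_block_gives_zero_f_and_unit_pairwise():
    X = np.tile(np.array([[41.0, 43.0, 45.0]]).T, (1, 3))
    res = rm_anova(X)
    assert res.F == 0.0
    assert all(p == 1.0 for _, p in res.pairwise)
    assert res.df_num == 2 and res.df_den == 4


def test_rm_anova_matches_pingouin_reference():
    """F, uncorrected/GG-corrected p, epsilons and Mauchly's test agree
    with an independent implementation within 1e-8."""
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    X = _fixture_block()
    res = rm_anova(X)
    long = pd.DataFrame({
        "y": X.ravel(),
        "subject": np.repeat(np.arange(X.shape[0]), 3),
        "time": np.tile(np.arange(3), X.shape[0]),
    })
    pg = pingouin.rm_anova(data=long, dv="y", within="time", subject="subject",
                           correction=True)
    assert res.F == pytest.approx(pg["F"].iloc[0], abs=1e-8)
    assert res.p_uncorrected == pytest.approx(pg["p_unc"].iloc[0], abs=1e-8)
    assert res.epsilon_gg == pytest.approx(pg["eps"].iloc[0], abs=1e-8)
    gg_p = stats.f.sf(res.F, res.df_num * res.epsilon_gg,
                      res.df_den * res.epsilon_gg)
    assert gg_p == pytest.approx(pg["p_GG_corr"].iloc[0], abs=1e-8)
    sph = pingouin.sphericity(long, dv="y", within="time", subject="subject")
    assert res.mauchly_W == pytest.approx(sph.W, abs=1e-8)
    assert res.mauchly_p == pytest.approx(sph.pval, abs=1e-8)
    eps_hf = pingouin.epsilon(long, dv="y", within="time", subject="subject",
                              correction="hf")
    assert res.epsilon_hf == pytest.approx(min(eps_hf, 1.0), abs=1e-8)


def test_two_timepoint_f_equals_squared_paired_t():
    rng = np.random.default_rng(5)
    X = rng.normal(40.0, 3.0, (12, 2))
    res = rm_anova(X, contrasts=((0, 1),))
    t = stats.ttest_rel(X[:, 0], X[:, 1]).statistic
    assert res.F == pytest.approx(t ** 2, rel=1e-10)


def test_epsilon_approaches_one_under_compound_symmetry():
    """Exchangeable covariance satisfies sphericity, so the GG epsilon
    concentrates near 1 as n grows (median over 200 reps at n=50)."""
    rng = np.random.default_rng(77)
    eps = []
    for _ in range(200):
        subject = rng.normal(0.0, 2.0, (50, 1))
        X = 40.0 + subject + rng.normal(0.0, 1.0, (50, 3))
        eps.append(rm_anova(X).epsilon_gg)
    assert np.median(eps) > 0.9


def test_bonferroni_pairwise_monotone_and_capped():
    X = _fixture_block()
    res2 = rm_anova(X, bonferroni_factor=2)
    res4 = rm_anova(X, bonferroni_factor=4)
    for (_, p2), (_, p4) in zip(res2.pairwise, res4.pairwise):
        assert p4 >= p2
        assert p2 <= 1.0 and p4 <= 1.0


def test_rm_anova_input_validation():
    with pytest.raises(ValueError):
        rm_anova(np.ones((2, 3)))
    with pytest.raises(ValueError):
        rm_anova(np.full((5, 3), np.nan))


def test_friedman_identical_columns_null():
    X = np.tile(np.array([[40.0, 41.0, 42.0, 43.0]]).T, (1, 3))
    chi2, df, p, pairwise = friedman_test(X)
    assert chi2 == 0.0 and p == 1.0 and df == 2
    assert all(pw == 1.0 for _, pw in pairwise)


def test_friedman_matches_hand_ranked_table():
    """4x3 table with unambiguous within-row ranks: chi2 from the rank
    formula 12/(nk(k+1)) * sum(R^2) - 3n(k+1)."""
    X = np.array([
        [1.0, 2.0, 3.0],
        [1.0, 2.0, 3.0],
        [2.0, 1.0, 3.0],
        [1.0, 3.0, 2.0],
    ])
    # column rank sums: R = [5, 8, 11]
    expected = 12.0 / (4 * 3 * 4) * (25 + 64 + 121) - 3 * 4 * 4
    chi2, df, p, _ = friedman_test(X)
    assert chi2 == pytest.approx(expected)
    assert p == pytest.approx(stats.chi2.sf(expected, 2))


def test_friedman_detects_monotone_shift():
    """Power smoke test: a 1-SD shift in one column is detected at
    p < 0.05 in at least 95% of 200 seeded replicates (n=40)."""
    rng = np.random.default_rng(123)
    hits = 0
    for _ in range(200):
        X = rng.normal(0.0, 1.0, (40, 3))
        X[:, 1] += 1.0
        hits += friedman_test(X)[2] < 0.05
    assert hits >= 190


def test_normality_screen_calibration_and_power():
    rng = np.random.default_rng(9)
    normal_pass = sum(
        normality_screen(rng.normal(0, 1, (200, 1)))[0]["passed"]
        for _ in range(100))
    exp_fail = sum(
        not normality_screen(rng.exponential(1.0, (200, 1)))[0]["passed"]
        for _ in range(100))
    assert normal_pass >= 90
    assert exp_fail >= 90


def test_normality_screen_zero_variance_fails_with_reason():
    out = normality_screen(np.ones((10, 1)))
    assert out[0]["passed"] is False
    assert out[0]["reason"] == "zero variance"


def test_combined_procedure_holds_type_one_error():
    """Full decision procedure (screen, then RM-ANOVA or Friedman) rejects
    at most 7% of 1,000 null blocks of n=19 at nominal alpha 0.05."""
    rng = np.random.default_rng(2026)
    rejections = 0
    for _ in range(1000):
        subject = rng.normal(42.0, 2.0, (19, 1))
        X = subject + rng.normal(0.0, 1.0, (19, 3))
        rejections += analyze_block(X)["p"] < 0.05
    assert rejections / 1000.0 <= 0.07
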