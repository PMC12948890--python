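"""Three-timepoint within-sample inference.

One-way repeated-measures ANOVA with Mauchly's sphericity test and
Greenhouse-Geisser / Huynh-Feldt corrections, Bonferroni-adjusted planned
paired comparisons (rest vs 21k and rest vs control), a tie-corrected
Friedman fallback for non-normal blocks, and a Lilliefors-style normality
screen (Kolmogorov-Smirnov with estimated parameters, plus skewness and
kurtosis bounds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "AnovaResult",
    "rm_anova",
    "friedman_test",
    "normality_screen",
    "analyze_block",
]


@dataclass
class AnovaResult:
    """Repeated-measures ANOVA outcome with sphericity handling.

    ``p_corrected`` is the p value after the applied epsilon correction
    (``correction_used`` is ``"none"`` when Mauchly's test does not reject
    sphericity).  ``pairwise`` lists ``(contrast, p_bonferroni)`` for the
    planned paired comparisons.
    """

    F: float
    df_num: float
    df_den: float
    p_uncorrected: float
    mauchly_W: float
    mauchly_p: float
    epsilon_gg: float
    epsilon_hf: float
    p_corrected: float
    correction_used: str
    pairwise: list = field(default_factory=list)


def _as_block(block) -> np.ndarray:
    X = np.asarray(block, dtype=float)
    if X.ndim != 2:
        raise ValueError("block must be a 2-D (samples x timepoints) array")
    if np.any(~np.isfinite(X)):
        raise ValueError("block must be complete-case (no missing cells)")
    return X


def rm_anova(
    block,
    contrasts: tuple = ((0, 1), (0, 2)),
    bonferroni_factor: int | None = None,
    alpha_sphericity: float = 0.05,
) -> AnovaResult:
    """One-way within-subject ANOVA across the columns of ``block``.

    Parameters
    ----------
    block : (n_samples, k) array
        Complete-case repeated measurements (columns rest, 21k, control
        for k = 3); ``n_samples >= 3`` required.
    contrasts : tuple of (i, j) column index pairs
        Planned paired comparisons; default rest-vs-21k and
        rest-vs-control.
    bonferroni_factor : int, optional
        Multiplier for the pairwise p values (defaults to the number of
        contrasts).

    Notes
    -----
    Mauchly's W is computed on the covariance of orthonormal contrasts of
    the columns, with the standard chi-square approximation.  When
    ``mauchly_p < alpha_sphericity`` the Greenhouse-Geisser correction is
    applied if ``epsilon_gg < 0.75``, otherwise Huynh-Feldt (clipped at 1).
    """
    X = _as_block(block)
    n, k = X.shape
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    if k < 2:
        raise ValueError("need at least 2 timepoints")

    grand = X.mean()
    col_means = X.mean(axis=0)
    row_means = X.mean(axis=1)
    ss_cond = n * np.sum((col_means - grand) ** 2)
    ss_subj = k * np.sum((row_means - grand) ** 2)
    ss_tot = np.sum((X - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df_num = k - 1.0
    df_den = (k - 1.0) * (n - 1.0)
    ms_cond = ss_cond / df_num
    ms_err = ss_err / df_den
    if ms_err <= 0:
        F = 0.0 if ss_cond <= 0 else float("inf")
    else:
        F = ms_cond / ms_err
    p_unc = float(stats.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0

    # orthonormal contrast covariance for sphericity diagnostics
    C = _orthonormal_contrasts(k)
    S = np.cov(X, rowvar=False, ddof=1)
    Sc = C @ S @ C.T
    eig = np.linalg.eigvalsh(Sc)
    eig = np.clip(eig, 0.0, None)
    tr = eig.sum()
    d = k - 1
    if tr <= 0:
        W, mauchly_p = 1.0, 1.0
        eps_gg = 1.0
    else:
        detSc = np.prod(eig)
        W = float(detSc / (tr / d) ** d) if tr > 0 else 1.0
        W = min(max(W, 0.0), 1.0)
        # chi-square approximation for Mauchly's statistic
        f_corr = 1.0 - (2.0 * d * d + d + 2.0) / (6.0 * d * (n - 1.0))
        chi2 = -(n - 1.0) * f_corr * np.log(W) if W > 0 else np.inf
        df_m = d * (d + 1.0) / 2.0 - 1.0
        mauchly_p = float(stats.chi2.sf(chi2, df_m)) if df_m > 0 else 1.0
        eps_gg = float(tr ** 2 / (d * np.sum(eig ** 2)))
    hf_den = d * (n - 1.0 - d * eps_gg)
    eps_hf = float((n * d * eps_gg - 2.0) / hf_den) if hf_den > 0 else 1.0
    eps_hf = min(eps_hf, 1.0)

    if k == 2:
        # sphericity is vacuous with a single contrast
        W, mauchly_p, eps_gg, eps_hf = 1.0, 1.0, 1.0, 1.0

    if mauchly_p < alpha_sphericity:
        correction = "gg" if eps_gg < 0.75 else "hf"
        eps = eps_gg if correction == "gg" else eps_hf
        p_corr = float(stats.f.sf(F, df_num * eps, df_den * eps))
    else:
        correction = "none"
        p_corr = p_unc

    factor = bonferroni_factor if bonferroni_factor is not None else len(contrasts)
    pairwise = []
    for (i, j) in contrasts:
        diff = X[:, i] - X[:, j]
        if np.allclose(diff.std(ddof=1), 0.0):
            p = 1.0 if np.allclose(diff.mean(), 0.0) else 0.0
        else:
            p = float(stats.ttest_rel(X[:, i], X[:, j]).pvalue)
        pairwise.append((f"col{i}_vs_col{j}", min(1.0, p * factor)))

    return AnovaResult(
        F=float(F), df_num=df_num, df_den=df_den, p_uncorrected=p_unc,
        mauchly_W=W, mauchly_p=float(mauchly_p),
        epsilon_gg=eps_gg, epsilon_hf=eps_hf,
        p_corrected=p_corr, correction_used=correction, pairwise=pairwise,
    )


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal basis of the space orthogonal to the mean."""
    H = np.linalg.qr(np.column_stack([np.ones(k), np.eye(k)[:, : k - 1]]))[0]
    return H[:, 1:].T


def friedman_test(
    block,
    contrasts: tuple = ((0, 1), (0, 2)),
    bonferroni_factor: int | None = None,
) -> tuple[float, int, float, list]:
    """Tie-corrected Friedman test across columns with Wilcoxon follow-ups.

    Returns ``(chi2, df, p, pairwise)`` where ``pairwise`` holds
    ``(contrast, p_bonferroni)`` from Wilcoxon signed-rank tests on the
    planned comparisons.  Constant rows are handled by midranks.
    """
    X = _as_block(block)
    n, k = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if np.allclose(X, X[:, [0]]):
        chi2, p = 0.0, 1.0
    else:
        chi2, p = stats.friedmanchisquare(*[X[:, j] for j in range(k)])
    factor = bonferroni_factor if bonferroni_factor is not None else len(contrasts)
    pairwise = []
    for (i, j) in contrasts:
        diff = X[:, i] - X[:, j]
        if np.allclose(diff, 0.0):
            pw = 1.0
        else:
            pw = float(stats.wilcoxon(X[:, i], X[:, j]).pvalue)
        pairwise.append((f"col{i}_vs_col{j}", min(1.0, pw * factor)))
    return float(chi2), k - 1, float(p), pairwise


def normality_screen(
    block,
    alpha: float = 0.05,
    max_abs_skew: float = 2.0,
    max_abs_kurtosis: float = 7.0,
) -> list:
    """Per-column normality screen: Lilliefors KS + skewness/kurtosis bounds.

    The Kolmogorov-Smirnov test uses the Lilliefors correction for
    estimated mean/SD (a naive KS with plug-in estimates would be
    anti-conservative).  A column passes when ``ks_p >= alpha`` and both
    |skewness| and |excess kurtosis| are below the configured bounds
    (defaults 2 and 7, the George & Mallery convention).  Zero-variance
    columns fail with reason ``"zero variance"``.
    """
    X = _as_block(block)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for the normality screen")
    out = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.std(col, ddof=1) == 0:
            out.append({"ks_p": float("nan"), "skewness": float("nan"),
                        "kurtosis": float("nan"), "passed": False,
                        "reason": "zero variance"})
            continue
        _, ks_p = lilliefors(col, dist="norm")
        skew = float(stats.skew(col, bias=False))
        kurt = float(stats.kurtosis(col, bias=False))  # excess kurtosis
        passed = (ks_p >= alpha and abs(skew) < max_abs_skew
                  and abs(kurt) < max_abs_kurtosis)
        out.append({"ks_p": float(ks_p), "skewness": skew, "kurtosis": kurt,
                    "passed": passed, "reason": None if passed else "screen failed"})
    return out


def analyze_block(block, alpha: float = 0.05) -> dict:
    """Full decision procedure for one region x subgroup block.

    Screens every column for normality; runs the repeated-measures ANOVA
    (with sphericity correction as needed) when all pass, otherwise the
    Friedman test.  Returns a flat dict of the test used, the omnibus p
    value and the Bonferroni pairwise p values.
    """
    screen = normality_screen(block, alpha=alpha)
    normal = all(c["passed"] for c in screen)
    if normal:
        res = rm_anova(block)
        return {
            "test": "rm_anova",
            "statistic": res.F,
            "p": res.p_corrected,
            "p_uncorrected": res.p_uncorrected,
            "mauchly_p": res.mauchly_p,
            "epsilon_gg": res.epsilon_gg,
            "epsilon_hf": res.epsilon_hf,
            "correction": res.correction_used,
            "pairwise": res.pairwise,
            "normality": screen,
        }
    chi2, df, p, pairwise = friedman_test(block)
    return {
        "test": "friedman",
        "statistic": chi2,
        "p": p,
        "df": df,
        "pairwise": pairwise,
        "normality": screen,
    }
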