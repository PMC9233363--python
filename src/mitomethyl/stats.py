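"""Per-site and cohort-level statistics.

The per-site machinery mirrors a low-n postmortem design: paired Wilcoxon
signed-rank tests between brain areas within individuals, per-site logistic
regressions of group on methylation with forensic covariates, and per-site
linear age associations. Cohort-level comparisons use Mann-Whitney and Pearson
chi-square (no continuity correction). Site selection is by raw P < alpha with
no multiple-testing adjustment — the selection rule the weighted indices are
built on, with the threshold exposed for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SiteTestResult",
    "WilcoxonResult",
    "paired_wilcoxon",
    "mann_whitney",
    "log_fold_change",
    "site_logistic",
    "site_age_association",
    "select_sites",
    "chi_square_independence",
    "pearson_power",
    "encode_covariates",
    "test_sites_paired_wilcoxon",
    "test_sites_logistic",
    "test_sites_age",
]


@dataclass(frozen=True)
class SiteTestResult:
    """Outcome of one per-site test.

    ``effect`` is the site weight candidate: a log fold change (brain-area
    contrast), a log odds ratio per percentage point (drug-use contrast) or an
    age slope in percent per year. Degenerate fits are flagged rather than
    emitted as infinities, and flagged results are excluded from selection.
    """

    site: tuple[int, str]
    effect: float
    p_value: float
    test_kind: str  # "log_fold_change" | "log_odds_ratio" | "age_slope"
    flagged: bool = False
    note: str = ""


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_used: int  # non-zero differences
    degenerate: bool = False


def _exact_signed_rank_sf_weights(ranks2: np.ndarray) -> np.ndarray:
    """Distribution of 2*W+ over all sign assignments, by convolution.

    ``ranks2`` are doubled mid-ranks (integers). Returns counts indexed by the
    doubled statistic, summing to 2**n.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def paired_wilcoxon(levels_a: Sequence[float], levels_b: Sequence[float]) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped (Wilcoxon's rule); ties among the absolute
    differences get mid-ranks. The null distribution is exact (full
    enumeration over sign assignments, tie-aware, via convolution) when the
    number of non-zero differences is at most 25, and a tie-corrected normal
    approximation otherwise. If every difference is zero the test is
    degenerate and P = 1.
    """
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_used=0, degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        ranks2 = np.rint(2 * ranks).astype(int)
        counts = _exact_signed_rank_sf_weights(ranks2)
        total = counts.sum()
        w2 = int(round(2 * w_plus))
        cdf = counts[: w2 + 1].sum() / total
        sf = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(cdf, sf))
    else:
        mean = ranks.sum() / 2.0
        var = float(np.sum(ranks**2)) / 4.0  # mid-ranks make this tie-corrected
        z = (w_plus - mean) / np.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
    return WilcoxonResult(statistic=w_plus, p_value=float(p), n_used=n)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when m + n <= 20 and there are no ties; otherwise
    a tie-corrected normal approximation (no continuity correction). Returns
    (U for the first sample, two-sided P).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if x.size + y.size <= 20 and no_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.statistic), float(res.pvalue)


def log_fold_change(mean_a: float, mean_b: float, pseudocount: float = 0.01) -> float:
    """Natural log of the ratio of two nonnegative group means.

    Used as the brain-area site weight: log fold change of the NAcc mean over
    the PFC mean. The pseudocount (in percent units; default 0.01, far below
    the ~2% working regime) keeps the ratio finite when a mean is zero.
    """
    if mean_a < 0 or mean_b < 0:
        raise ValueError("means must be nonnegative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    if pseudocount == 0 and (mean_a == 0 or mean_b == 0):
        raise ValueError("zero mean with zero pseudocount: fold change undefined")
    return float(np.log((mean_a + pseudocount) / (mean_b + pseudocount)))


def encode_covariates(covariates: pd.DataFrame | None) -> pd.DataFrame | None:
    """Numeric design columns for the adjustment covariates.

    Categorical columns (batch, collector, PMI class, ...) are dummy-coded
    with the first level dropped; booleans become 0/1. Returns None if there
    are no covariates.
    """
    if covariates is None or covariates.shape[1] == 0:
        return None
    enc = pd.get_dummies(covariates, drop_first=True, dtype=float)
    return enc.astype(float)


def _design(levels: np.ndarray, covariates: pd.DataFrame | None) -> np.ndarray:
    cols = [np.ones_like(levels), levels]
    if covariates is not None:
        cols.extend(np.asarray(covariates, dtype=float).T)
    return np.column_stack(cols)


def site_logistic(
    group_labels: Sequence,
    site_levels: Sequence[float],
    covariates: pd.DataFrame | None = None,
    positive_label="drug",
    site: tuple[int, str] = (0, "H"),
) -> SiteTestResult:
    """Covariate-adjusted logistic regression of group on one site's levels.

    Fits ``group ~ methylation_level + covariates`` and returns the
    methylation coefficient — the log odds ratio per percentage point — with
    its two-sided Wald P. Perfect separation, rank deficiency or
    non-convergence produce a flagged result (excluded from site selection)
    instead of an infinite effect. Covariates should already be encoded
    numerically (see :func:`encode_covariates`).
    """
    import warnings

    import statsmodels.api as sm

    y = (np.asarray(group_labels) == positive_label).astype(float)
    if y.min() == y.max():
        raise ValueError("both groups must be represented")
    levels = np.asarray(site_levels, dtype=float)
    if np.ptp(levels) == 0:
        return SiteTestResult(site, np.nan, np.nan, "log_odds_ratio", True, "constant levels")
    X = _design(levels, covariates)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return SiteTestResult(site, np.nan, np.nan, "log_odds_ratio", True, "rank deficient")
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation/convergence issues surface as flagged results instead
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta = float(fit.params[1])
        p = float(fit.pvalues[1])
        se = float(fit.bse[1])
        if not np.isfinite(beta) or not np.isfinite(p) or abs(beta) > 50 or se > 100:
            return SiteTestResult(
                site, np.nan, np.nan, "log_odds_ratio", True, "separation/unstable fit"
            )
    except Exception as exc:  # statsmodels raises on perfect separation
        return SiteTestResult(site, np.nan, np.nan, "log_odds_ratio", True, str(exc))
    return SiteTestResult(site, beta, p, "log_odds_ratio")


def site_age_association(
    site_levels: Sequence[float],
    ages: Sequence[float],
    covariates: pd.DataFrame | None = None,
    site: tuple[int, str] = (0, "H"),
) -> SiteTestResult:
    """Covariate-adjusted linear association of one site's levels with age.

    Fits ``methylation_level ~ age + covariates`` by least squares and returns
    the age coefficient (percent per year) with its two-sided P. With no
    covariates the coefficient equals r * (s_level / s_age), i.e. the slope
    implied by the Pearson correlation.
    """
    import statsmodels.api as sm

    ages = np.asarray(ages, dtype=float)
    levels = np.asarray(site_levels, dtype=float)
    if ages.size < 8:
        raise ValueError("need at least 8 samples")
    if np.ptp(ages) == 0:
        raise ValueError("ages must not be constant")
    if np.ptp(levels) == 0:
        return SiteTestResult(site, np.nan, np.nan, "age_slope", True, "constant levels")
    X = _design(ages, covariates)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return SiteTestResult(site, np.nan, np.nan, "age_slope", True, "rank deficient")
    fit = sm.OLS(levels, X).fit()
    slope, p = float(fit.params[1]), float(fit.pvalues[1])
    if not np.isfinite(slope) or not np.isfinite(p):
        return SiteTestResult(site, np.nan, np.nan, "age_slope", True, "degenerate fit")
    return SiteTestResult(site, slope, p, "age_slope")


def select_sites(results: Sequence[SiteTestResult], alpha: float) -> list[SiteTestResult]:
    """Retain unflagged results with P below the raw threshold.

    Deliberately applies no multiple-testing adjustment: the indices are built
    from the P < alpha Manhattan-plot rule, with alpha exposed (0.05 default;
    0.02 / 0.005 in sensitivity sweeps).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return [r for r in results if not r.flagged and r.p_value < alpha]


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction; df = (r-1)(c-1); upper-tail P. Zero row or
    column marginals are an error.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or np.any(tab < 0):
        raise ValueError("table must be a 2-D array of nonnegative counts")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("zero marginal row/column")
    chi2, p, dof, _ = sps.chi2_contingency(tab, correction=False)
    return float(chi2), int(dof), float(p)


def pearson_power(r: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-sided test of zero Pearson correlation, via Fisher z.

    power = Phi(delta - z_{1-alpha/2}) + Phi(-delta - z_{1-alpha/2}) with
    delta = sqrt(n-3) * atanh(r); the second (opposite-tail) term vanishes for
    any practically sized effect but keeps the r -> 0 limit equal to alpha.
    """
    if not 0 < r < 1:
        raise ValueError("r must be in (0, 1)")
    if n <= 3:
        raise ValueError("n must exceed 3")
    z_crit = sps.norm.ppf(1 - alpha / 2)
    delta = np.sqrt(n - 3) * np.arctanh(r)
    return float(sps.norm.cdf(delta - z_crit) + sps.norm.cdf(-delta - z_crit))


# ---------------------------------------------------------------------------
# matrix-wide per-site runs
# ---------------------------------------------------------------------------

def test_sites_paired_wilcoxon(
    levels_a: pd.DataFrame,
    levels_b: pd.DataFrame,
    pseudocount: float = 0.01,
) -> list[SiteTestResult]:
    """Paired Wilcoxon at every shared site; effect is the log fold change.

    Rows of the two level grids must be paired by individual (same index).
    The effect reported per site is the natural-log fold change of the group-A
    site mean over the group-B site mean.
    """
    if not levels_a.index.equals(levels_b.index):
        raise ValueError("rows must be paired by individual")
    shared = [c for c in levels_a.columns if c in set(levels_b.columns)]
    out = []
    for key in shared:
        a = levels_a[key].to_numpy(dtype=float)
        b = levels_b[key].to_numpy(dtype=float)
        res = paired_wilcoxon(a, b)
        effect = log_fold_change(float(a.mean()), float(b.mean()), pseudocount)
        out.append(
            SiteTestResult(
                site=key,
                effect=effect,
                p_value=res.p_value,
                test_kind="log_fold_change",
                flagged=res.degenerate,
                note="all differences zero" if res.degenerate else "",
            )
        )
    return out


def test_sites_logistic(
    levels: pd.DataFrame,
    group_labels: Sequence,
    covariates: pd.DataFrame | None = None,
) -> list[SiteTestResult]:
    """Per-site covariate-adjusted logistic regression across the matrix."""
    enc = encode_covariates(covariates)
    return [
        site_logistic(group_labels, levels[key].to_numpy(dtype=float), enc, site=key)
        for key in levels.columns
    ]


def test_sites_age(
    levels: pd.DataFrame,
    ages: Sequence[float],
    covariates: pd.DataFrame | None = None,
) -> list[SiteTestResult]:
    """Per-site covariate-adjusted age association across the matrix."""
    enc = encode_covariates(covariates)
    return [
        site_age_association(levels[key].to_numpy(dtype=float), ages, enc, site=key)
        for key in levels.columns
    ]


def results_to_frame(results: Sequence[SiteTestResult]) -> pd.DataFrame:
    """Tidy site-result table (the tabular form of a Manhattan/volcano plot)."""
    return pd.DataFrame(
        {
            "position": [r.site[0] for r in results],
            "strand": [r.site[1] for r in results],
            "effect": [r.effect for r in results],
            "p_value": [r.p_value for r in results],
            "test_kind": [r.test_kind for r in results],
            "flagged": [r.flagged for r in results],
        }
    )
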