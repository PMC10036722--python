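"""Evaluation statistics for segmentation accuracy and repeatability.

Covers the statistics used to validate volumetric segmentation: the Dice
similarity coefficient, two mean-absolute-percentage-error definitions (the
pair-mean-denominator form for test-retest repeatability and the
truth-denominator form for phantom accuracy), the coefficient of
repeatability (2.77 x within-subject SD), Bland-Altman limits of agreement,
ordinary regression/correlation, and ROC analysis via the Mann-Whitney
construction.  Nonparametric group tests (Mann-Whitney, Kruskal-Wallis with
Conover post hoc) are thin call-through utilities over standard
formulations; the bespoke content is the paired statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

ALPHA = 0.05  # two-sided significance level used throughout


@dataclass(frozen=True)
class PairedMeasurements:
    """Two measurements (ml) of the same subject, e.g. supine/prone scans."""

    subject: str
    x_s: float
    x_p: float

    def __post_init__(self) -> None:
        if self.x_s <= 0 or self.x_p <= 0:
            raise ValueError("paired measurements must be positive")


@dataclass(frozen=True)
class TruthReferenced:
    """A measured volume against its ground-truth value (ml)."""

    x_m: float
    x_actual: float

    def __post_init__(self) -> None:
        if self.x_actual <= 0:
            raise ValueError("truth volume must be positive")


def _pairs_to_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    if len(pairs) == 0:
        return np.empty(0), np.empty(0)
    if isinstance(pairs[0], PairedMeasurements):
        a = np.array([p.x_s for p in pairs], dtype=float)
        b = np.array([p.x_p for p in pairs], dtype=float)
    else:
        arr = np.asarray(pairs, dtype=float)
        a, b = arr[:, 0], arr[:, 1]
    return a, b


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) of two binary masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share the same grid")
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("Dice is undefined for two empty masks")
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def mape_paired(pairs) -> float:
    """Repeatability MAPE: 100/N * sum |x_s - x_p| / pair mean (percent)."""
    a, b = _pairs_to_arrays(pairs)
    if len(a) < 1:
        raise ValueError("need at least one pair")
    mean = (a + b) / 2.0
    if np.any(mean == 0):
        raise ValueError("pair mean of zero; MAPE undefined")
    return float(100.0 * np.mean(np.abs(a - b) / mean))


def mape_truth(items) -> float:
    """Accuracy MAPE: 100/N * sum |x_m - x_actual| / x_actual (percent)."""
    if len(items) == 0:
        raise ValueError("need at least one item")
    if isinstance(items[0], TruthReferenced):
        m = np.array([i.x_m for i in items], dtype=float)
        t = np.array([i.x_actual for i in items], dtype=float)
    else:
        arr = np.asarray(items, dtype=float)
        m, t = arr[:, 0], arr[:, 1]
    if len(m) < 1:
        raise ValueError("need at least one item")
    if np.any(t == 0):
        raise ValueError("zero truth volume; MAPE undefined")
    return float(100.0 * np.mean(np.abs(m - t) / np.abs(t)))


@dataclass(frozen=True)
class RepeatabilityResult:
    within_subject_sd: float
    cr: float  # 2.77 * within-subject SD
    cr_ci: tuple[float, float]  # chi-square 95% CI


def coefficient_of_repeatability(pairs) -> RepeatabilityResult:
    """CR = 2.77 x within-subject SD from paired measurements.

    The within-subject SD comes from the one-way pairs model,
    ``s_w = sqrt(sum d_i^2 / (2N))``; the 95% CI uses the chi-square
    distribution of ``N s_w^2 / sigma^2`` with N degrees of freedom.
    """
    a, b = _pairs_to_arrays(pairs)
    n = len(a)
    if n < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    s_w = float(np.sqrt(np.sum(d**2) / (2.0 * n)))
    lo_q, hi_q = sps.chi2.ppf([1 - ALPHA / 2, ALPHA / 2], df=n)
    ci = (2.77 * s_w * np.sqrt(n / lo_q), 2.77 * s_w * np.sqrt(n / hi_q))
    return RepeatabilityResult(within_subject_sd=s_w, cr=2.77 * s_w, cr_ci=ci)


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa: tuple[float, float]  # mean +/- 1.96 SD
    mean_ci: tuple[float, float]
    loa_lower_ci: tuple[float, float]
    loa_upper_ci: tuple[float, float]
    percent_mode: bool


def bland_altman(pairs, percent_mode: bool = True) -> BlandAltmanResult:
    """Bland-Altman agreement summary of paired measurements.

    In percent mode each difference is expressed as a percentage of the pair
    mean (the percentage volume difference convention); limits of agreement
    are mean +/- 1.96 SD, with t-based 95% CIs for the mean and the limits.
    """
    a, b = _pairs_to_arrays(pairs)
    n = len(a)
    if n < 3:
        raise ValueError("need at least three pairs")
    diff = a - b
    if percent_mode:
        diff = 100.0 * diff / ((a + b) / 2.0)
    m = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    loa = (m - 1.96 * sd, m + 1.96 * sd)
    t = sps.t.ppf(1 - ALPHA / 2, df=n - 1)
    se_mean = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(1.0 / n + 1.96**2 / (2.0 * (n - 1)))
    return BlandAltmanResult(
        mean_diff=m,
        sd_diff=sd,
        loa=loa,
        mean_ci=(m - t * se_mean, m + t * se_mean),
        loa_lower_ci=(loa[0] - t * se_loa, loa[0] + t * se_loa),
        loa_upper_ci=(loa[1] - t * se_loa, loa[1] + t * se_loa),
        percent_mode=percent_mode,
    )


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    r: float
    r_ci: tuple[float, float]
    p_value: float


def regression_and_correlation(x, y) -> RegressionResult:
    """OLS trend line and Pearson correlation of measured vs true volumes.

    Slope CI is t-based; the correlation CI uses the Fisher z transform; the
    p value is the two-sided test of zero correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least three points")
    if np.ptp(x) == 0:
        raise ValueError("regression undefined for constant x")
    res = sps.linregress(x, y)
    t = sps.t.ppf(1 - ALPHA / 2, df=n - 2)
    slope_ci = (res.slope - t * res.stderr, res.slope + t * res.stderr)
    r = res.rvalue
    if abs(r) < 1.0 and n > 3:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        zc = sps.norm.ppf(1 - ALPHA / 2)
        r_ci = (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))
    else:
        r_ci = (r, r)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_ci=slope_ci,
        r=float(r),
        r_ci=r_ci,
        p_value=float(res.pvalue),
    )


@dataclass(frozen=True)
class ROCResult:
    auc: float
    auc_ci: tuple[float, float]
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float


def roc_analysis(scores, labels, threshold: float | None = None) -> ROCResult:
    """ROC analysis of a score against binary labels.

    AUC by the Mann-Whitney construction (ties count one half), which equals
    trapezoidal integration of the empirical ROC curve; the CI uses the
    Hanley-McNeil standard error.  With no threshold given, the
    Youden-optimal threshold (max sensitivity + specificity - 1) is reported;
    classification calls scores >= threshold positive.  Sensitivity,
    specificity and accuracy are on the 0-100 scale.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos, neg = s[y], s[~y]
    n1, n0 = len(pos), len(neg)
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    auc = float(wins / (n1 * n0))
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    se = np.sqrt(
        max(auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2), 0.0)
        / (n1 * n0)
    )
    zc = sps.norm.ppf(1 - ALPHA / 2)
    auc_ci = (max(0.0, auc - zc * se), min(1.0, auc + zc * se))
    if threshold is None:
        cands = np.unique(s)
        youden = [
            ((pos >= c).mean() + (neg < c).mean() - 1.0, c) for c in cands
        ]
        threshold = max(youden)[1]
    tp = float((pos >= threshold).sum())
    tn = float((neg < threshold).sum())
    sens = 100.0 * tp / n1
    spec = 100.0 * tn / n0
    acc = 100.0 * (tp + tn) / (n1 + n0)
    return ROCResult(
        auc=auc,
        auc_ci=auc_ci,
        threshold=float(threshold),
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
    )


def roc_curve_points(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC curve (FPR, TPR), for plotting and the AUC identity."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1], [-np.inf]])
    tpr = [(s[y] >= t).mean() for t in thresholds]
    fpr = [(s[~y] >= t).mean() for t in thresholds]
    return np.array(fpr), np.array(tpr)


# ---------------------------------------------------------------------------
# Nonparametric group comparisons (call-through utilities)
# ---------------------------------------------------------------------------


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test: returns (U, p)."""
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis_conover(groups: dict[str, np.ndarray]) -> dict:
    """Kruskal-Wallis ANOVA with Conover-Iman post hoc pairwise tests.

    Returns the omnibus H and p plus a p value per group pair; the post hoc
    p values use the t distribution on rank statistics, uncorrected.
    """
    names = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in names]
    H, p = sps.kruskal(*samples)
    all_vals = np.concatenate(samples)
    ranks = sps.rankdata(all_vals)
    n = len(all_vals)
    k = len(samples)
    sizes = [len(s) for s in samples]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(k)]
    # Conover's pooled variance of ranks
    s2 = (np.sum(ranks**2) - n * (n + 1) ** 2 / 4.0) / (n - 1)
    posthoc = {}
    for i, j in combinations(range(k), 2):
        se = np.sqrt(s2 * ((n - 1 - H) / (n - k)) * (1.0 / sizes[i] + 1.0 / sizes[j]))
        t_stat = abs(mean_ranks[i] - mean_ranks[j]) / se
        posthoc[(names[i], names[j])] = float(
            2 * sps.t.sf(t_stat, df=n - k)
        )
    return {"H": float(H), "p": float(p), "posthoc": posthoc}


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test (call-through): returns (W, p)."""
    res = sps.shapiro(np.asarray(values, dtype=float))
    return float(res.statistic), float(res.pvalue)
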