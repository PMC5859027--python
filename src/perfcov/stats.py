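"""Paired diagnostic-comparison statistics.

ROC/AUC with DeLong's paired test, Youden-index cutoff selection, McNemar
paired tests on discordant counts, ordinary-least-squares regression with
an intercept confidence interval, Bland-Altman agreement, and 2x2
concordance at a score threshold.  All p-values are two-tailed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "RocComparison",
    "AgreementReport",
    "roc_auc",
    "delong_paired_test",
    "optimal_cutoff",
    "mcnemar_test",
    "bland_altman",
    "concordance_at_threshold",
    "observed_agreement_from_counts",
    "linreg_with_ci",
    "agreement_report",
]

#: Discordant-pair count at which McNemar switches from the exact binomial
#: to the continuity-corrected chi-square.
MCNEMAR_EXACT_LIMIT = 25


@dataclass(frozen=True)
class RocComparison:
    """Paired AUCs with DeLong covariance-based comparison."""

    auc_a: float
    auc_b: float
    se_a: float
    se_b: float
    ci95_a: tuple[float, float]
    ci95_b: tuple[float, float]
    auc_diff: float
    se_diff: float
    z: float
    delong_p: float
    degenerate: bool = False


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman + regression + threshold-concordance summary.

    Differences are oriented ``b - a`` (3-slice minus whole-heart in the
    pipeline); the regression is of ``a`` (whole-heart) on ``b`` (3-slice).
    """

    n: int
    bias: float
    loa_low: float
    loa_high: float
    bias_ci95: tuple[float, float]
    bias_p: float
    sd_diff: float
    slope: float
    intercept: float
    intercept_ci95: tuple[float, float]
    r_squared: float
    concordance_table: dict[str, int]
    observed_agreement: float


def _split_classes(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC estimate; tied score pairs count one half."""
    pos, neg = _split_classes(np.asarray(scores), np.asarray(labels))
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    m = len(pos)
    u = ranks[:m].sum() - m * (m + 1) / 2.0
    return float(u / (m * len(neg)))


def _delong_components(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return psi.mean(axis=1), psi.mean(axis=0), float(psi.mean())


def delong_paired_test(scores_a, scores_b, labels) -> RocComparison:
    """Compare two paired AUCs via DeLong's covariance estimate.

    Both score vectors must refer to the same subjects in the same order.
    A degenerate (zero-variance) difference reports p = 1 with the
    ``degenerate`` flag set.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must have the same length")
    pos_a, neg_a = _split_classes(scores_a, labels)
    pos_b, neg_b = _split_classes(scores_b, labels)
    m, n = len(pos_a), len(neg_a)

    v10_a, v01_a, auc_a = _delong_components(pos_a, neg_a)
    v10_b, v01_b, auc_b = _delong_components(pos_b, neg_b)

    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n

    se_a = math.sqrt(max(cov[0, 0], 0.0))
    se_b = math.sqrt(max(cov[1, 1], 0.0))
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = auc_a - auc_b

    degenerate = var_diff <= 0 or not math.isfinite(var_diff)
    if degenerate:
        z, p = 0.0, 1.0
    else:
        z = diff / math.sqrt(var_diff)
        p = 2.0 * sps.norm.sf(abs(z))

    zcrit = 1.959963984540054
    return RocComparison(
        auc_a=auc_a,
        auc_b=auc_b,
        se_a=se_a,
        se_b=se_b,
        ci95_a=(auc_a - zcrit * se_a, auc_a + zcrit * se_a),
        ci95_b=(auc_b - zcrit * se_b, auc_b + zcrit * se_b),
        auc_diff=diff,
        se_diff=math.sqrt(max(var_diff, 0.0)),
        z=z,
        delong_p=float(min(p, 1.0)),
        degenerate=degenerate,
    )


def optimal_cutoff(scores, labels) -> float:
    """Youden-J-maximizing threshold over observed score values.

    The decision rule is ``score >= threshold``; ties in J break toward the
    lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _split_classes(scores, np.asarray(labels))
    best_t, best_j = None, -np.inf
    for t in np.unique(scores):
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, float(t)
    return best_t


def mcnemar_test(n01: int, n10: int) -> float:
    """Two-tailed McNemar p on discordant-pair counts.

    Exact binomial (sign test) when the discordant total is below
    ``MCNEMAR_EXACT_LIMIT``, continuity-corrected chi-square otherwise.
    """
    if n01 < 0 or n10 < 0 or n01 != int(n01) or n10 != int(n10):
        raise ValueError("discordant counts must be non-negative integers")
    n = int(n01) + int(n10)
    if n == 0:
        return 1.0
    if n < MCNEMAR_EXACT_LIMIT:
        k = min(int(n01), int(n10))
        return float(min(1.0, 2.0 * sps.binom.cdf(k, n, 0.5)))
    stat = (abs(n01 - n10) - 1.0) ** 2 / n
    return float(sps.chi2.sf(stat, df=1))


def bland_altman(a, b) -> dict:
    """Bland-Altman agreement of paired measurements, differences ``b - a``.

    Returns bias, 95% limits of agreement (bias ± 1.96·SD of differences),
    a t-based 95% CI for the bias, and the paired two-tailed t-test p.
    Zero-variance differences are handled (p = 1, LoA collapse to the bias).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two 1-D arrays of equal length")
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    diff = b - a
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    tcrit = float(sps.t.ppf(0.975, df=n - 1))
    sem = sd / math.sqrt(n)
    if sd == 0.0:
        p = 1.0
    else:
        tstat = bias / sem
        p = float(2.0 * sps.t.sf(abs(tstat), df=n - 1))
    return {
        "n": n,
        "bias": bias,
        "sd_diff": sd,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "bias_ci95": (bias - tcrit * sem, bias + tcrit * sem),
        "bias_p": p,
    }


def concordance_at_threshold(a, b, threshold: float = 3.0) -> dict:
    """2x2 dichotomization counts of two paired scores at one threshold."""
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired scores must have equal length")
    ap = a >= threshold
    bp = b >= threshold
    table = {
        "both_pos": int(np.sum(ap & bp)),
        "both_neg": int(np.sum(~ap & ~bp)),
        "a_only": int(np.sum(ap & ~bp)),
        "b_only": int(np.sum(~ap & bp)),
    }
    table["observed_agreement"] = observed_agreement_from_counts(
        table["both_pos"], table["both_neg"], table["a_only"], table["b_only"]
    )
    return table


def observed_agreement_from_counts(
    both_pos: int, both_neg: int, a_only: int, b_only: int
) -> float:
    """Percent observed agreement from 2x2 concordance counts."""
    total = both_pos + both_neg + a_only + b_only
    if total <= 0:
        raise ValueError("empty concordance table")
    return 100.0 * (both_pos + both_neg) / total


def linreg_with_ci(x, y) -> dict:
    """OLS of y on x with a t-based 95% CI for the intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need two 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    res = sps.linregress(x, y)
    tcrit = float(sps.t.ppf(0.975, df=len(x) - 2))
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "intercept_ci95": (
            float(res.intercept - tcrit * res.intercept_stderr),
            float(res.intercept + tcrit * res.intercept_stderr),
        ),
        "r_squared": float(res.rvalue**2),
    }


def agreement_report(a, b, threshold: float = 3.0) -> AgreementReport:
    """Full agreement analysis of paired scores (a = reference, b = test).

    Combines Bland-Altman of ``b - a``, regression of ``a`` on ``b``, and
    2x2 concordance at ``threshold``.
    """
    ba = bland_altman(a, b)
    reg = linreg_with_ci(np.asarray(b, dtype=float), np.asarray(a, dtype=float))
    conc = concordance_at_threshold(a, b, threshold)
    return AgreementReport(
        n=ba["n"],
        bias=ba["bias"],
        loa_low=ba["loa_low"],
        loa_high=ba["loa_high"],
        bias_ci95=ba["bias_ci95"],
        bias_p=ba["bias_p"],
        sd_diff=ba["sd_diff"],
        slope=reg["slope"],
        intercept=reg["intercept"],
        intercept_ci95=reg["intercept_ci95"],
        r_squared=reg["r_squared"],
        concordance_table={
            k: conc[k] for k in ("both_pos", "both_neg", "a_only", "b_only")
        },
        observed_agreement=conc["observed_agreement"],
    )
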