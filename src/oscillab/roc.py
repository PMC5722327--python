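"""ROC analysis, optimal cut-off, AUC banding and AUC-based sample size.

The AUC is computed by the Mann-Whitney pair-counting statistic (ties
count one half), which is identical to the trapezoidal area under the
empirical ROC curve.  Curves are auto-oriented so that AUC >= 0.5,
recording whether higher or lower feature values indicate disease.

The optimal operating point maximizes the Youden index
J = Se + Sp - 100 (percent scale); ties are broken toward higher
specificity, then toward the lower threshold.

Diagnostic-accuracy bands: AUC in [0.50, 0.70) low, [0.70, 0.90)
moderate, [0.90, 1.00] high (edges belong to the higher band), with
0.75 as the minimum AUC for adequate clinical accuracy.

Sample size follows Hanley & McNeil's normal-approximation theory for
testing an observed AUC against a null value, using the large-sample
AUC variance with equal group sizes n:

    Var(A) ~ (Q1 + Q2 - 2 A^2) / n,
    Q1 = A / (2 - A),  Q2 = 2 A^2 / (1 + A)

The smallest n satisfying  z_alpha * SE0 + z_beta * SE1 <= A1 - A0  is
returned.  The sidedness of alpha is configurable; the two-sided
convention (the default, as used by the common clinical sample-size
software) gives 20 per group for 0.75 vs 0.5 at alpha = beta = 0.10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import ClassBalanceError, OrientationError

ADEQUACY_MIN_AUC = 0.75


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve, auto-oriented so that AUC >= 0.5."""

    thresholds: np.ndarray  # in natural feature units
    fpr: np.ndarray  # 1 - Sp, fraction
    tpr: np.ndarray  # Se, fraction
    auc: float
    orientation: str  # "higher_is_positive" | "lower_is_positive"


@dataclass(frozen=True)
class CutoffResult:
    threshold: float  # natural units; positive if score >= (or <=) threshold
    se: float  # %
    sp: float  # %
    youden: float  # Se + Sp - 100
    orientation: str


def mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Pair-counting AUC: P(pos > neg) + 0.5 P(pos = neg), via ranks."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    combined = np.concatenate([pos, neg])
    ranks = sps.rankdata(combined)
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """Empirical ROC curve with Mann-Whitney AUC and auto-orientation.

    ``labels`` is binary with 1 = diseased/positive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ClassBalanceError("both classes must be present")

    auc = mann_whitney_auc(pos, neg)
    if auc >= 0.5:
        orientation = "higher_is_positive"
        oriented = scores
    else:
        orientation = "lower_is_positive"
        oriented = -scores
        auc = 1.0 - auc

    # sweep thresholds over the oriented scores, "positive if score >= t"
    thr = np.unique(oriented)[::-1]
    tpr = np.empty(thr.size + 1)
    fpr = np.empty(thr.size + 1)
    opos = oriented[labels == 1]
    oneg = oriented[labels == 0]
    for i, t in enumerate(thr):
        tpr[i] = np.mean(opos >= t)
        fpr[i] = np.mean(oneg >= t)
    tpr[-1], fpr[-1] = 1.0, 1.0  # threshold below the minimum
    # natural-unit thresholds (undo the orientation flip)
    natural = thr if orientation == "higher_is_positive" else -thr
    natural = np.append(natural, np.nan)
    return RocCurve(thresholds=natural, fpr=fpr, tpr=tpr, auc=auc,
                    orientation=orientation)


def trapezoidal_auc(curve: RocCurve) -> float:
    """Area under the empirical curve by the trapezoid rule (with (0,0))."""
    fpr = np.concatenate([[0.0], curve.fpr])
    tpr = np.concatenate([[0.0], curve.tpr])
    return float(np.trapezoid(tpr, fpr))


def optimal_cutoff(curve: RocCurve) -> CutoffResult:
    """Youden-maximizing operating point.

    Ties in J are broken toward higher specificity, then toward the
    lower threshold.  The final all-positive point (nan threshold) is
    not a usable cut-off and is excluded.
    """
    se = 100.0 * curve.tpr[:-1]
    sp = 100.0 * (1.0 - curve.fpr[:-1])
    j = se + sp - 100.0
    best = 0
    for i in range(1, j.size):
        if j[i] > j[best] + 1e-12:
            best = i
        elif abs(j[i] - j[best]) <= 1e-12:
            if sp[i] > sp[best] + 1e-12:
                best = i
            elif abs(sp[i] - sp[best]) <= 1e-12 and \
                    curve.thresholds[i] < curve.thresholds[best]:
                best = i
    return CutoffResult(threshold=float(curve.thresholds[best]),
                        se=float(se[best]), sp=float(sp[best]),
                        youden=float(j[best]), orientation=curve.orientation)


def auc_band(auc: float) -> Tuple[str, bool]:
    """(accuracy band, adequate-for-clinical-use flag) of an oriented AUC."""
    if auc < 0.5:
        raise OrientationError("AUC below 0.5: orient the curve first")
    if auc > 1.0:
        raise ValueError("AUC cannot exceed 1")
    if auc < 0.70:
        band = "low"
    elif auc < 0.90:
        band = "moderate"
    else:
        band = "high"
    return band, bool(auc >= ADEQUACY_MIN_AUC)


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Exact Hanley-McNeil standard error of an empirical AUC."""
    a = auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1.0 - a) + (n_pos - 1) * (q1 - a * a)
           + (n_neg - 1) * (q2 - a * a)) / (n_pos * n_neg)
    return math.sqrt(var)


def auc_confidence_interval(auc: float, n_pos: int, n_neg: int,
                            level: float = 0.95) -> Tuple[float, float]:
    """Normal-approximation CI for the AUC with the Hanley-McNeil SE."""
    se = hanley_mcneil_se(auc, n_pos, n_neg)
    z = sps.norm.ppf(0.5 + level / 2.0)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def _variance_slope(auc: float) -> float:
    """Large-sample per-group variance slope of the AUC (equal groups)."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    return q1 + q2 - 2.0 * auc * auc


def hanley_mcneil_min_n(auc_alt: float = 0.75, auc_null: float = 0.5,
                        alpha: float = 0.10, beta: float = 0.10,
                        sided: str = "two") -> int:
    """Smallest equal per-group n detecting ``auc_alt`` against ``auc_null``.

    Returns the smallest n for which the normal-approximation power
    inequality  z_alpha * SE0(n) + z_beta * SE1(n) <= auc_alt - auc_null
    holds, with the AUC variance evaluated under the null and the
    alternative via the large-sample Hanley-McNeil slopes.
    """
    if not (0.5 <= auc_null < auc_alt <= 1.0):
        raise ValueError("require 0.5 <= auc_null < auc_alt <= 1")
    if not (0 < alpha < 1 and 0 < beta < 1):
        raise ValueError("alpha and beta must be in (0, 1)")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    z_a = sps.norm.ppf(1.0 - (alpha / 2.0 if sided == "two" else alpha))
    z_b = sps.norm.ppf(1.0 - beta)
    delta = auc_alt - auc_null
    v0 = _variance_slope(auc_null)
    v1 = _variance_slope(auc_alt)
    n = 2
    while z_a * math.sqrt(v0 / n) + z_b * math.sqrt(v1 / n) > delta:
        n += 1
        if n > 10**7:  # pragma: no cover - guards degenerate input
            raise RuntimeError("sample-size search did not converge")
    return n
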