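"""Group comparisons and correlation analysis for feature tables.

The decision logic mirrors standard biostatistical practice for small
physiological cohorts: a Shapiro-Wilk normality gate routes each
analysis either to the parametric branch (one-way ANOVA with Tukey
pairwise tests; Pearson correlation) or to the non-parametric branch
(Kruskal-Wallis with pairwise Mann-Whitney; Spearman correlation).
Differences with p <= 0.05 are considered significant (inclusive).

Correlation strength is banded by |r|:

    [0, 0.25)     small or none
    [0.25, 0.50)  reasonable
    [0.50, 0.75)  moderate to good
    [0.75, 1]     very good to excellent

(band edges belong to the higher band; banding is symmetric in sign).

Because many correlations are examined jointly, a modified Bonferroni
correction divides the base significance level by the effective number
of independent correlations: the oscillometry features reduce to two
independent axes (resistive and reactive), each crossed with the
comparator exam's independent variables.  With four comparator
variables this gives 2 x 4 = 8 and a corrected level of
0.05 / 8 = 0.0063 (reported to four decimals, half-up).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, UndefinedCorrelationError

BANDS = (
    (0.25, "small or no correlation"),
    (0.50, "reasonable"),
    (0.75, "moderate to good"),
    (np.inf, "very good to excellent"),
)


def band_label(r: float) -> str:
    """Correlation-strength band of |r|; edges belong to the higher band."""
    a = abs(r)
    if a > 1:
        raise ValueError("|r| must not exceed 1")
    if a < 0.25:
        return BANDS[0][1]
    if a < 0.50:
        return BANDS[1][1]
    if a < 0.75:
        return BANDS[2][1]
    return BANDS[3][1]


@dataclass(frozen=True)
class CorrectedAlpha:
    """Modified Bonferroni significance level for correlation analyses."""

    raw: float
    reported: float
    n_effective: int
    base_alpha: float


def corrected_alpha(n_fot_vars: int = 2, n_other_vars: int = 4,
                    base_alpha: float = 0.05) -> CorrectedAlpha:
    """base_alpha divided by the effective number of independent correlations."""
    if n_fot_vars < 1 or n_other_vars < 1:
        raise ValueError("variable counts must be positive integers")
    n_eff = int(n_fot_vars) * int(n_other_vars)
    raw = base_alpha / n_eff
    reported = float(Decimal(repr(raw)).quantize(Decimal("0.0001"),
                                                 rounding=ROUND_HALF_UP))
    return CorrectedAlpha(raw=raw, reported=reported, n_effective=n_eff,
                          base_alpha=base_alpha)


def _shapiro_p(x: np.ndarray) -> float:
    """Shapiro-Wilk p-value; degenerate samples count as non-normal."""
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(x).pvalue)


@dataclass(frozen=True)
class GroupComparisonResult:
    feature: str
    normality_p: Dict[str, float]
    test_used: str  # "anova_tukey" | "kruskal_mannwhitney"
    omnibus_p: float
    pairwise_p: Dict[Tuple[str, str], float]
    significant: bool
    alpha: float
    n_comparisons: int


def compare_groups(table: pd.DataFrame, feature: str,
                   group_col: str = "group",
                   alpha: float = 0.05) -> GroupComparisonResult:
    """Omnibus + pairwise comparison of one feature across groups.

    Shapiro-Wilk is applied per group at ``alpha``; only when every
    group passes is the parametric branch used.  Pairwise p-values are
    reported raw (uncorrected), with the comparison count recorded.
    """
    sub = table[[group_col, feature]].dropna()
    labels = list(dict.fromkeys(sub[group_col]))
    if len(labels) < 2:
        raise InsufficientDataError("need at least two groups")
    samples = [sub.loc[sub[group_col] == g, feature].to_numpy(dtype=float)
               for g in labels]
    for g, x in zip(labels, samples):
        if x.size < 3:
            raise InsufficientDataError(f"group {g!r} has fewer than 3 observations")

    normality = {g: _shapiro_p(x) for g, x in zip(labels, samples)}
    pairwise: Dict[Tuple[str, str], float] = {}
    if all(p > alpha for p in normality.values()):
        test_used = "anova_tukey"
        omnibus_p = float(sps.f_oneway(*samples).pvalue)
        tuk = sps.tukey_hsd(*samples)
        for i, j in itertools.combinations(range(len(labels)), 2):
            pairwise[(labels[i], labels[j])] = float(tuk.pvalue[i, j])
    else:
        test_used = "kruskal_mannwhitney"
        omnibus_p = float(sps.kruskal(*samples).pvalue)
        for i, j in itertools.combinations(range(len(labels)), 2):
            mw = sps.mannwhitneyu(samples[i], samples[j], alternative="two-sided")
            pairwise[(labels[i], labels[j])] = float(mw.pvalue)
    return GroupComparisonResult(
        feature=feature, normality_p=normality, test_used=test_used,
        omnibus_p=omnibus_p, pairwise_p=pairwise,
        significant=bool(omnibus_p <= alpha), alpha=alpha,
        n_comparisons=len(pairwise),
    )


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    method: str  # "pearson" | "spearman"
    band: str
    passes_corrected_alpha: bool
    alpha_used: float


def correlate_pair(x: Sequence[float], y: Sequence[float],
                   alpha: float = 0.05,
                   corrected: Optional[CorrectedAlpha] = None) -> CorrelationResult:
    """Correlation between two paired variables with the normality gate.

    Pearson when both variables pass Shapiro-Wilk at ``alpha``,
    Spearman otherwise.  Significance of the correlation is judged at
    the modified Bonferroni level (default ``corrected_alpha()``, i.e.
    0.05 / 8); the raw (unrounded) corrected level is used for the
    decision.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired")
    if x.size < 4:
        raise InsufficientDataError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in a variable")
    corrected = corrected or corrected_alpha()
    if _shapiro_p(x) > alpha and _shapiro_p(y) > alpha:
        res = sps.pearsonr(x, y)
        method = "pearson"
    else:
        res = sps.spearmanr(x, y)
        method = "spearman"
    r = float(res.statistic if hasattr(res, "statistic") else res.correlation)
    p = float(res.pvalue)
    return CorrelationResult(
        r=r, p=p, method=method, band=band_label(r),
        passes_corrected_alpha=bool(p <= corrected.raw),
        alpha_used=corrected.raw,
    )


def compare_all_features(table: pd.DataFrame, features: Sequence[str],
                         group_col: str = "group",
                         alpha: float = 0.05) -> pd.DataFrame:
    """Tidy frame of :func:`compare_groups` over several features."""
    rows = []
    for feat in features:
        res = compare_groups(table, feat, group_col=group_col, alpha=alpha)
        row = {"feature": feat, "test_used": res.test_used,
               "omnibus_p": res.omnibus_p, "significant": res.significant}
        for (a, b), p in res.pairwise_p.items():
            row[f"p_{a}_vs_{b}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
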