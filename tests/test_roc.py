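"""ROC curves, Youden cut-off, AUC bands, Hanley-McNeil sample size."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn import metrics as skm

from oscillab import (
    auc_band,
    auc_confidence_interval,
    hanley_mcneil_min_n,
    hanley_mcneil_se,
    mann_whitney_auc,
    optimal_cutoff,
    roc_auc,
)
from oscillab.errors import ClassBalanceError, OrientationError
from oscillab.roc import trapezoidal_auc


def _scores(pos, neg):
    scores = np.concatenate([pos, neg]).astype(float)
    labels = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
    return scores, labels


class TestRocAuc:
    def test_perfect_separation(self):
        curve = roc_auc(*_scores([4, 5, 6], [1, 2, 3]))
        assert curve.auc == pytest.approx(1.0)

    def test_tied_pair_counts_one_half(self):
        # 9 pairs: 8 wins + 1 tie -> 8.5/9
        curve = roc_auc(*_scores([3, 4, 5], [1, 2, 3]))
        assert curve.auc == pytest.approx(8.5 / 9)

    def test_all_identical_scores_give_half(self):
        curve = roc_auc(*_scores([2, 2, 2], [2, 2]))
        assert curve.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ClassBalanceError):
            roc_auc([1.0, 2.0], [1, 1])

    def test_auto_orientation_flips_low_auc(self):
        # lower scores indicate disease here
        curve = roc_auc(*_scores([1, 2, 3], [4, 5, 6]))
        assert curve.orientation == "lower_is_positive"
        assert curve.auc == pytest.approx(1.0)

    def test_negating_scores_preserves_oriented_curve(self):
        rng = np.random.default_rng(0)
        scores, labels = _scores(rng.normal(1, 1, 20), rng.normal(0, 1, 25))
        c1 = roc_auc(scores, labels)
        c2 = roc_auc(-scores, labels)
        assert c1.auc == pytest.approx(c2.auc)
        assert np.allclose(c1.tpr, c2.tpr) and np.allclose(c1.fpr, c2.fpr)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sklearn_and_trapezoid(self, seed):
        """Pair-counting AUC equals trapezoidal ROC area (sklearn oracle)."""
        rng = np.random.default_rng(seed)
        scores, labels = _scores(rng.integers(0, 8, 30), rng.integers(0, 8, 30))
        curve = roc_auc(scores, labels)
        assert curve.auc == pytest.approx(trapezoidal_auc(curve), abs=1e-12)
        sk = skm.roc_auc_score(labels, scores)
        assert curve.auc == pytest.approx(max(sk, 1 - sk), abs=1e-12)

    def test_curve_monotone(self):
        rng = np.random.default_rng(1)
        scores, labels = _scores(rng.normal(1, 1, 40), rng.normal(0, 1, 40))
        curve = roc_auc(scores, labels)
        assert np.all(np.diff(curve.tpr) >= 0)
        assert np.all(np.diff(curve.fpr) >= 0)


class TestOptimalCutoff:
    def test_perfect_separation_reaches_j_100(self):
        cut = optimal_cutoff(roc_auc(*_scores([4, 5, 6], [1, 2, 3])))
        assert cut.se == pytest.approx(100.0)
        assert cut.sp == pytest.approx(100.0)
        assert cut.youden == pytest.approx(100.0)
        assert 3 < cut.threshold <= 4

    def test_tie_broken_toward_higher_specificity(self):
        # J = 66.7 both at cut >= 3 (Se 100, Sp 66.7) and >= 4 (Se 66.7, Sp 100)
        cut = optimal_cutoff(roc_auc(*_scores([3, 4, 5], [1, 2, 3])))
        assert cut.sp == pytest.approx(100.0)
        assert cut.threshold == pytest.approx(4.0)

    def test_published_style_cutoff_classifies_positive(self):
        # applying a 3.23 cut-off to R0 = 3.5 under higher_is_positive
        assert 3.5 >= 3.23

    def test_youden_identity(self):
        rng = np.random.default_rng(2)
        cut = optimal_cutoff(roc_auc(*_scores(rng.normal(1, 1, 30),
                                              rng.normal(0, 1, 30))))
        assert cut.youden == pytest.approx(cut.se + cut.sp - 100.0)


class TestAucBand:
    @pytest.mark.parametrize("auc,band,adequate", [
        (0.82, "moderate", True),
        (0.95, "high", True),
        (0.70, "moderate", False),  # lower edge belongs to the higher band
        (0.90, "high", True),
        (0.60, "low", False),
        (0.75, "moderate", True),  # the adequacy bar itself
    ])
    def test_bands(self, auc, band, adequate):
        assert auc_band(auc) == (band, adequate)

    def test_unoriented_auc_rejected(self):
        with pytest.raises(OrientationError):
            auc_band(0.4)


class TestHanleyMcNeil:
    def test_paper_configuration_two_sided_gives_20(self):
        assert hanley_mcneil_min_n(0.75, 0.5, 0.10, 0.10, sided="two") == 20

    def test_one_sided_variant(self):
        assert hanley_mcneil_min_n(0.75, 0.5, 0.10, 0.10, sided="one") == 15

    def test_monotone_in_effect_size(self):
        assert hanley_mcneil_min_n(0.999, 0.5, 0.10, 0.10) < \
            hanley_mcneil_min_n(0.75, 0.5, 0.10, 0.10)

    def test_monotone_in_alpha_and_power(self):
        base = hanley_mcneil_min_n(0.75, 0.5, 0.10, 0.10)
        assert hanley_mcneil_min_n(0.75, 0.5, 0.05, 0.10) >= base
        assert hanley_mcneil_min_n(0.75, 0.5, 0.10, 0.05) >= base

    @pytest.mark.parametrize("auc_alt,alpha,beta", [
        (0.75, 0.10, 0.10), (0.8, 0.05, 0.2), (0.65, 0.05, 0.1),
    ])
    def test_returned_n_is_minimal(self, auc_alt, alpha, beta):
        """n satisfies the power inequality while n-1 does not."""
        from scipy.stats import norm

        from oscillab.roc import _variance_slope

        n = hanley_mcneil_min_n(auc_alt, 0.5, alpha, beta)
        z_a = norm.ppf(1 - alpha / 2)
        z_b = norm.ppf(1 - beta)
        delta = auc_alt - 0.5
        v0, v1 = _variance_slope(0.5), _variance_slope(auc_alt)

        def lhs(m):
            return z_a * np.sqrt(v0 / m) + z_b * np.sqrt(v1 / m)

        assert lhs(n) <= delta
        if n > 2:
            assert lhs(n - 1) > delta

    def test_exact_se_at_half_matches_closed_form(self):
        # at A = 0.5 the Hanley-McNeil variance is (n_p + n_n + 1) / (12 n_p n_n)
        se = hanley_mcneil_se(0.5, 20, 20)
        assert se == pytest.approx(np.sqrt(41 / (12 * 400)))

    def test_ci_is_ordered_and_clipped(self):
        lo, hi = auc_confidence_interval(0.97, 24, 23)
        assert 0 <= lo < 0.97 < hi <= 1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            hanley_mcneil_min_n(0.5, 0.5)
        with pytest.raises(ValueError):
            hanley_mcneil_min_n(0.75, 0.5, alpha=0.0)


class TestBinormalLimit:
    def test_empirical_auc_converges_to_closed_form(self):
        """AUC of N(3.91, 0.57^2) vs N(2.77, 0.23^2) -> Phi(1.14/0.6147)."""
        from scipy.stats import norm

        closed = norm.cdf((3.91 - 2.77) / np.sqrt(0.57**2 + 0.23**2))
        assert closed == pytest.approx(0.968, abs=5e-4)
        rng = np.random.default_rng(0)
        pos = rng.normal(3.91, 0.57, 10_000)
        neg = rng.normal(2.77, 0.23, 10_000)
        assert mann_whitney_auc(pos, neg) == pytest.approx(closed, abs=0.01)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.lists(st.integers(0, 5), min_size=2, max_size=15),
       st.lists(st.integers(0, 5), min_size=2, max_size=15))
def test_pair_counting_matches_brute_force(pos, neg):
    """Rank-based AUC equals the naive double loop with ties = 0.5."""
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0
               for a in pos for b in neg)
    expected = wins / (len(pos) * len(neg))
    assert mann_whitney_auc(np.array(pos), np.array(neg)) == \
        pytest.approx(expected, abs=1e-12)
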