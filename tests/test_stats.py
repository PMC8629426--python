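"""Rank statistics and ROC/Youden analysis against independent oracles."""

import itertools
import warnings

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

import icikinetics as ik


def _enumeration_oracle(x, y):
    """Independent exact two-tailed rank-sum p: enumerate every split of the
    pooled values (multiset) into groups of the observed sizes."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    nx = len(x)
    e_w = nx * (len(pooled) + 1) / 2.0
    w_obs = ranks[:nx].sum()
    extreme = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        w = ranks[list(idx)].sum()
        extreme += abs(w - e_w) >= abs(w_obs - e_w) - 1e-12
        total += 1
    return extreme / total


class TestWilcoxonRankSum:
    def test_identical_samples_give_p_one(self):
        x = [1.0, 2.0, 3.0]
        _, p = ik.wilcoxon_rank_sum(x, x)
        assert p == 1.0

    def test_fully_separated_small_samples(self):
        # 2 of the C(6,3)=20 rank splits are as extreme: p = 0.1
        _, p = ik.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_branch_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=5)
        y = rng.normal(0.8, size=6)
        _, p = ik.wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(_enumeration_oracle(x, y))

    def test_exact_branch_handles_ties(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [2.0, 3.0, 3.0, 4.0]
        _, p = ik.wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(_enumeration_oracle(x, y))

    def test_exact_matches_scipy_when_no_ties(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=6), rng.normal(1.0, size=6)
        _, p = ik.wilcoxon_rank_sum(x, y)
        expected = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_and_approximate_branches_agree_at_crossover(self, seed):
        """Just past the exact-enumeration cutoff the continuity-corrected
        normal approximation tracks the exact p closely. (The exhaustive
        worst case over all achievable rank sums at N = 12-13 is ~0.016-0.018
        absolute, so 0.02 is the attainable bound for this approximation.)"""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6)
        y = rng.normal(0.5, size=6)
        _, p_approx = ik.wilcoxon_rank_sum(np.r_[x, x[-1] + 0.013], y)  # N = 13
        p_exact13 = _enumeration_oracle(np.r_[x, x[-1] + 0.013], y)
        assert abs(p_approx - p_exact13) < 0.02

    def test_large_sample_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=30), rng.normal(0.6, size=30)
        w, p = ik.wilcoxon_rank_sum(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)
        # W (rank sum of x) relates to U by the fixed offset n_x(n_x+1)/2
        assert w - 30 * 31 / 2 == pytest.approx(ref.statistic)

    def test_all_identical_pooled_values(self):
        _, p = ik.wilcoxon_rank_sum(np.ones(20), np.ones(25))
        assert p == 1.0

    def test_one_sided_orientation(self):
        _, p_greater = ik.wilcoxon_rank_sum([4, 5, 6], [1, 2, 3], two_tailed=False)
        assert p_greater == pytest.approx(1 / 20)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([0.2, 1.5, 3.0, 7.0])
        assert ik.spearman(x, np.exp(x)) == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert ik.spearman(x, x[::-1]) == pytest.approx(-1.0)

    def test_hand_ranked_fixture(self):
        # ranks (1,2,3,4) vs (1,3,2,4): rho = 1 - 6*2/(4*15) = 0.8
        assert ik.spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_invariant_under_increasing_transform(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = ik.spearman(x, y)
        assert ik.spearman(np.exp(x), y) == pytest.approx(base)
        assert ik.spearman(x, 3 * y + 7) == pytest.approx(base)

    def test_constant_input_signaled(self):
        with pytest.raises(ValueError):
            ik.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = ik.confusion_metrics(10, 0, 10, 0)
        assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.accuracy) == (1, 1, 1, 1, 1)

    def test_hand_computed_mixture(self):
        m = ik.confusion_metrics(8, 6, 20, 2)
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(20 / 26)
        assert m.ppv == pytest.approx(8 / 14)
        assert m.npv == pytest.approx(20 / 22)
        assert m.accuracy == pytest.approx(28 / 36)

    def test_scale_invariance(self):
        a = ik.confusion_metrics(8, 6, 20, 2)
        b = ik.confusion_metrics(24, 18, 60, 6)
        assert a == b

    def test_zero_denominator_signaled_not_zeroed(self):
        with pytest.warns(UserWarning, match="ppv"):
            m = ik.confusion_metrics(0, 0, 5, 5)
        assert np.isnan(m.ppv)
        assert m.specificity == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ik.confusion_metrics(0, 0, 0, 0)


def _brute_force_roc(scores, labels, thr):
    pred = scores >= thr
    tp = np.sum(pred & labels)
    fn = np.sum(~pred & labels)
    tn = np.sum(~pred & ~labels)
    fp = np.sum(pred & ~labels)
    return tp / (tp + fn), tn / (tn + fp)


class TestRocWithYouden:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9, 1.0])
        labels = np.array([0, 0, 0, 1, 1, 1], bool)
        roc = ik.roc_with_youden(scores, labels)
        assert roc.youden_j == pytest.approx(1.0)
        assert roc.metrics.accuracy == 1.0
        assert roc.auc == pytest.approx(1.0)
        assert 0.3 < roc.youden_threshold < 0.8

    def test_uninformative_scores(self):
        scores = np.ones(10)
        labels = np.array([1, 0] * 5, bool)
        roc = ik.roc_with_youden(scores, labels)
        assert roc.youden_j == pytest.approx(0.0)
        assert roc.auc == pytest.approx(0.5)

    def test_scan_matches_brute_force_confusion_counts(self, rng):
        scores = rng.normal(size=10)
        labels = rng.random(10) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        roc = ik.roc_with_youden(scores, labels)
        for i, thr in enumerate(roc.thresholds):
            sens, spec = _brute_force_roc(scores, labels, thr)
            assert roc.sensitivity[i] == pytest.approx(sens)
            assert roc.specificity[i] == pytest.approx(spec)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_auc_equals_normalized_mann_whitney_u(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=40), 1)  # rounding induces ties
        labels = rng.random(40) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        roc = ik.roc_with_youden(scores, labels)
        u = sps.mannwhitneyu(scores[labels], scores[~labels]).statistic
        assert roc.auc == pytest.approx(u / (labels.sum() * (~labels).sum()))
        assert roc.auc == pytest.approx(roc_auc_score(labels, scores))

    def test_tie_break_picks_smallest_threshold(self):
        # two thresholds attain the same J; the smaller favors sensitivity
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([0, 1, 0, 1], bool)
        roc = ik.roc_with_youden(scores, labels)
        j = roc.sensitivity + roc.specificity - 1.0
        ties = roc.thresholds[j == j.max()]
        assert roc.youden_threshold == ties.min()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ik.roc_with_youden([1.0, 2.0], [True, True])
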