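import numpy as np
import pytest

from hlamatch.classify import (
    ClassificationError,
    ClassifierConfig,
    accuracy_at,
    feature_addition_curve,
    fit_model,
    loocv_scores,
    rank_candidates,
    roc_auc,
    run_loocv,
    sensitivity_specificity,
)
from hlamatch.features import FeatureMatrix, build_feature_matrix


def pairwise_auc(scores, labels):
    """Mann-Whitney oracle: (#concordant + 0.5 #tied) / (#pos #neg)."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ordering(self):
        _, auc = roc_auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        _, auc = roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert auc == 0.5

    def test_three_of_four_concordant(self):
        _, auc = roc_auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert auc == 0.75

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2], labels[-2:] = 1, 0
        roc, _ = roc_auc(scores, labels)
        assert tuple(roc[0]) == (0.0, 0.0) and tuple(roc[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc[:, 0]) >= 0) and np.all(np.diff(roc[:, 1]) >= 0)

    def test_matches_mann_whitney_on_random_instances(self, rng):
        for _ in range(50):
            n = rng.integers(6, 40)
            scores = rng.choice(rng.random(5), size=n)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ClassificationError):
            roc_auc([0.1, 0.2], [1, 1])


class TestThresholdMetrics:
    def test_accuracy_examples(self):
        assert accuracy_at([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert accuracy_at([0.9, 0.1, 0.9, 0.1], [1, 1, 0, 0]) == 0.5

    def test_boundary_thresholds(self):
        scores, labels = [0.2, 0.5, 0.8, 0.9], [0, 1, 0, 1]
        assert sensitivity_specificity(scores, labels, 0.0) == (1.0, 0.0)
        assert sensitivity_specificity(scores, labels, 1.1) == (0.0, 1.0)

    def test_no_positives_rejected(self):
        with pytest.raises(ClassificationError, match="sensitivity"):
            sensitivity_specificity([0.1, 0.9], [0, 0], 0.5)

    def test_threshold_sweep_consistent_with_roc(self, rng):
        scores = np.round(rng.random(30), 1)
        labels = rng.integers(0, 2, 30)
        labels[:2], labels[-2:] = 1, 0
        roc, _ = roc_auc(scores, labels)
        roc_set = {(round(f, 12), round(t, 12)) for f, t in roc}
        for t in np.unique(scores):
            sens, spec = sensitivity_specificity(scores, labels, t)
            assert (round(1 - spec, 12), round(sens, 12)) in roc_set
            n = len(labels)
            n_pos = labels.sum()
            acc = accuracy_at(scores, labels, t)
            assert acc == pytest.approx((sens * n_pos + spec * (n - n_pos)) / n)


class TestLoocv:
    def _signal_matrix(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        y = np.repeat([1, 0], n // 2)
        x = y * 2.0 + 0.05 * rng.standard_normal(n)
        X = np.column_stack([x, rng.standard_normal(n)])
        return X, y

    def test_one_score_per_couple_and_determinism(self, small_dataset):
        fm = build_feature_matrix(small_dataset.cohort, small_dataset.functions)
        cfg = ClassifierConfig(seed=1)
        s1 = loocv_scores(fm.values, fm.y, cfg)
        s2 = loocv_scores(fm.values, fm.y, cfg)
        assert s1.shape == (len(small_dataset.cohort),)
        np.testing.assert_array_equal(s1, s2)

    def test_identical_features_give_chance_auc(self):
        X = np.ones((12, 3))
        y = np.repeat([1, 0], 6)
        with pytest.warns(UserWarning, match="zero-variance"):
            scores = loocv_scores(X, y, ClassifierConfig())
        assert np.allclose(scores, scores[0])
        _, auc = roc_auc(scores, y)
        assert auc == 0.5

    def test_separable_feature_orders_classes(self):
        X, y = self._signal_matrix()
        scores = loocv_scores(X, y, ClassifierConfig())
        _, auc = roc_auc(scores, y)
        assert auc == 1.0

    def test_flipping_held_out_label_does_not_leak(self):
        """The held-out couple's label must not touch its own fold model."""
        X, y = self._signal_matrix(n=16, seed=3)
        cfg = ClassifierConfig()
        base = loocv_scores(X, y, cfg)
        for i in (0, 7, 15):
            y_flipped = y.copy()
            y_flipped[i] = 1 - y_flipped[i]
            flipped = loocv_scores(X, y_flipped, cfg)
            assert flipped[i] == base[i]

    def test_single_class_cohort_rejected(self):
        X = np.random.default_rng(0).standard_normal((8, 2))
        with pytest.raises(ClassificationError):
            loocv_scores(X, np.array([1, 1, 1, 1, 1, 1, 1, 0]), ClassifierConfig())

    def test_calibrations_agree_on_ordering_for_a_fixed_model(self, small_dataset):
        """For one trained model both calibrations are monotone in the
        decision value, so they rank new couples identically."""
        fm = build_feature_matrix(small_dataset.cohort, small_dataset.functions)
        m_platt = fit_model(fm, ClassifierConfig(calibration="platt"))
        m_rank = fit_model(fm, ClassifierConfig(calibration="rank"))
        p1 = m_platt.predict_proba(fm.values)
        p2 = m_rank.predict_proba(fm.values)
        np.testing.assert_array_equal(np.argsort(p1, kind="stable"),
                                      np.argsort(p2, kind="stable"))

    def test_run_loocv_summary_consistency(self, signal_dataset):
        result = run_loocv(signal_dataset.true_features, ClassifierConfig())
        assert result.auc == pytest.approx(
            pairwise_auc(result.scores, result.labels), abs=1e-12
        )
        for t, (sens, spec) in result.threshold_table.items():
            s2, sp2 = sensitivity_specificity(result.scores, result.labels, t)
            assert (sens, spec) == (s2, sp2)


class TestFeatureAdditionCurve:
    def test_last_point_equals_full_model(self, small_dataset):
        fm = build_feature_matrix(small_dataset.cohort, small_dataset.functions)
        cfg = ClassifierConfig()
        curve = feature_addition_curve(fm, cfg)
        assert [k for k, _ in curve] == list(range(1, 10))
        full = roc_auc(loocv_scores(fm.values, fm.y, cfg), fm.y)[1]
        assert curve[-1][1] == pytest.approx(full, abs=1e-12)

    def test_duplicated_feature_gives_flat_curve(self):
        # an informative feature keeps the per-fold decision direction
        # stable, so duplicating it cannot change any score ordering
        rng = np.random.default_rng(2)
        y = np.repeat([1, 0], 8)
        x = y + 0.8 * rng.standard_normal(16)
        fm = FeatureMatrix(
            couple_ids=[f"c{i}" for i in range(16)],
            columns=tuple(("A", f"f{j}") for j in range(9)),
            values=np.tile(x[:, None], (1, 9)),
            labels=np.where(y == 1, "RM", "control"),
        )
        curve = feature_addition_curve(fm, ClassifierConfig())
        aucs = {round(a, 12) for _, a in curve}
        assert len(aucs) == 1


class TestRanking:
    def test_dissimilar_candidate_ranked_first_under_similarity_risk(self, signal_dataset):
        """With labels driven by high couple similarity, the most dissimilar
        donor should get the lowest predicted risk."""
        fm = signal_dataset.true_features
        model = fit_model(fm, ClassifierConfig())
        recipient = signal_dataset.cohort.couples[0].maternal
        similar = ("similar", dict(recipient))
        pools = {l: signal_dataset.cohort.alleles_at(l) for l in "ABC"}
        f1 = signal_dataset.functions
        # pick, per locus, the pool allele least similar to the recipient's
        dissimilar_half = {}
        for locus in "ABC":
            a0 = recipient[locus][0]
            worst = min(pools[locus], key=lambda a: f1[(locus, "f1")](a0, a))
            dissimilar_half[locus] = (worst, worst)
        ranked = rank_candidates(
            recipient, [similar, ("dissimilar", dissimilar_half)], model,
            signal_dataset.functions,
        )
        assert ranked[0][0] == "dissimilar"
        assert ranked[0][1] < ranked[1][1]

    def test_single_candidate_returned_alone(self, signal_dataset):
        model = fit_model(signal_dataset.true_features, ClassifierConfig())
        recipient = signal_dataset.cohort.couples[0].maternal
        half = signal_dataset.cohort.couples[1].paternal
        ranked = rank_candidates(recipient, [("only", dict(half))], model,
                                 signal_dataset.functions)
        assert len(ranked) == 1 and ranked[0][0] == "only"
        assert 0.0 <= ranked[0][1] <= 1.0

    def test_duplicate_candidates_stay_adjacent(self, signal_dataset):
        model = fit_model(signal_dataset.true_features, ClassifierConfig())
        recipient = signal_dataset.cohort.couples[0].maternal
        half = dict(signal_dataset.cohort.couples[1].paternal)
        ranked = rank_candidates(
            recipient, [("dup", half), ("dup", half), ("zzz", half)], model,
            signal_dataset.functions,
        )
        assert [cid for cid, _ in ranked] == ["dup", "dup", "zzz"]
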