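"""Fusion strategies: weighted averaging, mean/majority voting, fuzzy fusion."""

import numpy as np
import pytest
from sklearn.base import clone

from avifuse import (FuzzyCombiner, MajorityVoteCombiner, MeanVoteCombiner,
                     WeightedAverageCombiner, combine_weighted, fuse_panel,
                     fuzzy_combine, majority_vote, mean_vote)
from avifuse.panel import LabelVocabulary, PredictionPanel

from conftest import make_row


def random_row(rng, m=3, k=4):
    p = rng.dirichlet(np.ones(k), size=m)
    return make_row(p)


class TestCombineWeighted:
    def test_convexity_fixed_point(self, rng):
        p = rng.dirichlet(np.ones(5))
        row = make_row([p, p, p])
        res = combine_weighted(row, [0.2, 0.5, 0.3])
        np.testing.assert_allclose(res.probs, p, atol=1e-12)

    def test_degenerate_weight_selects_model(self, rng):
        row = random_row(rng)
        res = combine_weighted(row, [1.0, 0.0, 0.0])
        np.testing.assert_allclose(res.probs, row[0].probs, atol=1e-12)

    def test_three_model_fixed_weights(self):
        # the 0.3/0.3/0.4 fixed-weight configuration, by hand:
        # 0.3*(1,0) + 0.3*(1,0) + 0.4*(0,1) = (0.6, 0.4)
        row = make_row([[1, 0], [1, 0], [0, 1]])
        res = combine_weighted(row, [0.3, 0.3, 0.4])
        np.testing.assert_allclose(res.probs, [0.6, 0.4], atol=1e-12)
        assert res.predicted_index == 0

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="weights"):
            combine_weighted(random_row(rng, m=3), [0.5, 0.5])

    def test_permutation_equivariance(self, rng):
        row = random_row(rng)
        w = np.array([0.2, 0.3, 0.5])
        perm = [2, 0, 1]
        res = combine_weighted(row, w)
        res_p = combine_weighted([row[i] for i in perm], w[perm])
        np.testing.assert_allclose(res.probs, res_p.probs, atol=1e-12)


class TestMeanVote:
    def test_single_model(self, rng):
        row = random_row(rng, m=1)
        np.testing.assert_allclose(mean_vote(row).probs, row[0].probs)

    def test_hand_example(self):
        row = make_row([[0.8, 0.2], [0.4, 0.6]])
        np.testing.assert_allclose(mean_vote(row).probs, [0.6, 0.4], atol=1e-12)

    def test_equals_uniform_weighted(self, rng):
        for _ in range(10):
            row = random_row(rng, m=4)
            np.testing.assert_array_equal(
                mean_vote(row).probs,
                combine_weighted(row, np.full(4, 0.25)).probs)

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mean_vote([])


class TestMajorityVote:
    def test_modal_label_wins(self):
        row = make_row([[0.6, 0.4, 0], [0.7, 0.3, 0], [0.1, 0.8, 0.1]])
        res = majority_vote(row)
        assert res.predicted_index == 0
        assert res.probs[0] == pytest.approx(2 / 3)

    def test_tie_broken_by_confidence(self):
        # three-way label tie A/B/C with confidences 0.5/0.9/0.6 -> B
        row = make_row([[0.5, 0.3, 0.2], [0.05, 0.9, 0.05], [0.2, 0.2, 0.6]])
        assert majority_vote(row).predicted_index == 1

    def test_matches_counting_oracle(self, rng):
        for _ in range(30):
            row = random_row(rng, m=5, k=3)
            res = majority_vote(row)
            counts = np.bincount([mp.predicted_index for mp in row], minlength=3)
            assert counts[res.predicted_index] == counts.max()
            np.testing.assert_allclose(res.probs, counts / 5)


class TestFuzzyCombine:
    def test_equal_confidence_equals_mean_vote(self, fis3, rng):
        # symmetry of the rule base: identical confidences give uniform weights
        for _ in range(100):
            k = int(rng.integers(3, 6))
            conf = rng.uniform(0.4, 0.95)
            rows = []
            for _ in range(3):
                rest = rng.dirichlet(np.ones(k - 1)) * (1 - conf)
                p = np.concatenate([[conf], rest])
                if rest.max() >= conf:  # keep confidence the max entry
                    continue
                rows.append(p)
            if len(rows) < 3:
                continue
            row = make_row(rows)
            res = fuzzy_combine(row, fis3)
            np.testing.assert_allclose(res.probs, mean_vote(row).probs, atol=1e-9)

    def test_weights_recorded_and_convex(self, fis3, rng):
        row = random_row(rng)
        res = fuzzy_combine(row, fis3)
        assert res.weights.shape == (3,)
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_arity_mismatch_rejected(self, fis3, rng):
        with pytest.raises(ValueError, match="models"):
            fuzzy_combine(random_row(rng, m=2), fis3)

    def test_confident_model_dominates(self, fis3):
        row = make_row([[0.97, 0.01, 0.02], [0.4, 0.35, 0.25], [0.36, 0.4, 0.24]])
        res = fuzzy_combine(row, fis3)
        assert res.weights[0] == max(res.weights)
        assert res.predicted_index == 0


class TestInvariants:
    def test_all_strategies_output_normalized(self, fis3, rng):
        for _ in range(20):
            row = random_row(rng)
            for res in (mean_vote(row), majority_vote(row),
                        combine_weighted(row, [0.3, 0.3, 0.4]),
                        fuzzy_combine(row, fis3)):
                assert np.all(res.probs >= 0)
                assert res.probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_confidence_convexity_bound(self, fis3, rng):
        # fused confidence cannot exceed the largest single-model mass on the
        # chosen class
        for _ in range(20):
            row = random_row(rng)
            for res in (mean_vote(row), combine_weighted(row, [0.2, 0.5, 0.3]),
                        fuzzy_combine(row, fis3)):
                cap = max(mp.probs[res.predicted_index] for mp in row)
                assert res.confidence <= cap + 1e-9


class TestEstimators:
    def _X(self, rng, n=20, m=3, k=4):
        return rng.dirichlet(np.ones(k), size=(n, m))

    def test_mean_combiner_matches_function(self, rng):
        X = self._X(rng)
        comb = MeanVoteCombiner().fit(X)
        fused = comb.predict_proba(X)
        for i in range(len(X)):
            np.testing.assert_allclose(fused[i], mean_vote(make_row(X[i])).probs,
                                       atol=1e-12)

    def test_weighted_combiner_validates_weights(self, rng):
        X = self._X(rng)
        with pytest.raises(ValueError):
            WeightedAverageCombiner(weights=[0.7, 0.7, 0.1]).fit(X)

    def test_2d_input_with_n_classes(self, rng):
        X3 = self._X(rng)
        X2 = X3.reshape(len(X3), -1)
        a = MeanVoteCombiner().fit(X3).predict_proba(X3)
        b = MeanVoteCombiner(n_classes=4).fit(X2).predict_proba(X2)
        np.testing.assert_allclose(a, b)

    def test_predict_uses_class_labels(self, rng):
        X = self._X(rng, k=3)
        comb = MajorityVoteCombiner(classes=["a", "b", "c"]).fit(X)
        labels = comb.predict(X)
        assert set(labels) <= {"a", "b", "c"}

    def test_clone_and_get_params(self):
        comb = FuzzyCombiner(mode="panel_average", n_classes=4)
        cloned = clone(comb)
        assert cloned.get_params()["mode"] == "panel_average"

    def test_fuzzy_estimator_weights_shape(self, rng):
        X = self._X(rng, n=10)
        comb = FuzzyCombiner().fit(X)
        comb.predict_proba(X)
        assert comb.weights_.shape == (10, 3)
        np.testing.assert_allclose(comb.weights_.sum(axis=1), 1.0, atol=1e-9)

    def test_panel_average_mode_single_weight_vector(self, rng):
        X = self._X(rng, n=15)
        comb = FuzzyCombiner(mode="panel_average").fit(X)
        comb.predict_proba(X)
        assert np.ptp(comb.weights_, axis=0).max() < 1e-12

    def test_unfitted_rejected(self, rng):
        with pytest.raises(RuntimeError, match="not fitted"):
            MeanVoteCombiner().predict_proba(self._X(rng))


class TestFusePanel:
    def test_strategies_on_panel(self, rng):
        vocab = LabelVocabulary(("a", "b", "c"))
        probs = rng.dirichlet(np.ones(3), size=(5, 2))
        panel = PredictionPanel(vocab, [f"s{i}" for i in range(5)],
                                ["m1", "m2"], probs)
        for strategy in ("mean", "majority", "fuzzy"):
            results = fuse_panel(panel, strategy=strategy)
            assert len(results) == 5
            assert all(r.strategy == strategy for r in results)
        results = fuse_panel(panel, strategy="weighted", weights=[0.6, 0.4])
        np.testing.assert_allclose(results[0].probs,
                                   0.6 * probs[0, 0] + 0.4 * probs[0, 1])

    def test_weighted_requires_weights(self, rng):
        vocab = LabelVocabulary(("a", "b"))
        panel = PredictionPanel(vocab, ["s"], ["m1", "m2"],
                                rng.dirichlet(np.ones(2), size=(1, 2)))
        with pytest.raises(ValueError, match="weights"):
            fuse_panel(panel, strategy="weighted")
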