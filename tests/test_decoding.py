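"""Tests of sparse logistic decoding, CV fold choice, boundary distance
and the chi-square association machinery."""

import numpy as np
import pytest

from latentrl import decoding
from latentrl.decoding import (CONF_WINDOWS, DecoderModel,
                               SubjectAssociationData, boundary_distance,
                               chi2_2x2, chi2_association, choose_k_folds,
                               state_likelihood, train_slr)


class TestChooseKFolds:
    @pytest.mark.parametrize("n,k", [(100, 10), (99, 11), (101, 10)])
    def test_examples(self, n, k):
        assert choose_k_folds(n) == k

    def test_exhaustive_remainder_minimization(self):
        for n in range(11, 501):
            k = choose_k_folds(n)
            best = min((n % kk, -kk) for kk in (9, 10, 11))
            assert (n % k, -k) == best

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            choose_k_folds(10)


def _planted(n_trials, n_voxels, n_informative, effect, seed):
    rng = np.random.default_rng(seed)
    labels = np.arange(n_trials) % 2
    X = rng.standard_normal((n_trials, n_voxels))
    informative = rng.choice(n_voxels, n_informative, replace=False)
    X[:, informative] += (effect / 2.0) * (labels * 2 - 1)[:, None]
    return X, labels, informative


class TestTrainSLR:
    def test_planted_voxel_recall(self):
        X, labels, informative = _planted(200, 150, 30, 2.5, seed=0)
        model = train_slr(X, labels, n_iterations=3, seed=0)
        support = set(model.support)
        recall = len(support & set(informative)) / max(1, len(support))
        assert recall >= 0.5
        assert model.cv_accuracy[model.chosen_iteration - 1] > 0.85

    def test_weights_only_on_selected_voxels(self):
        X, labels, _ = _planted(120, 60, 15, 2.0, seed=1)
        model = train_slr(X, labels, n_iterations=2, seed=1)
        selected = {v for it in model.selected_voxels for v in it}
        assert set(model.support) <= selected

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((40, 10))
        with pytest.raises(ValueError):
            train_slr(X, np.zeros(40, dtype=int))

    def test_label_permutation_near_chance(self):
        # permutation property: mean CV accuracy over permuted-label
        # fits stays inside the chance band
        X, labels, _ = _planted(100, 50, 10, 2.0, seed=2)
        rng = np.random.default_rng(3)
        accs = []
        for _ in range(8):
            perm = rng.permutation(labels)
            m = train_slr(X, perm, n_iterations=2, seed=4)
            accs.append(m.cv_accuracy[m.chosen_iteration - 1])
        assert np.mean(accs) == pytest.approx(0.5, abs=0.12)


class TestBoundaryDistance:
    def _model(self, w, b=0.0):
        return DecoderModel(weights=np.asarray(w, float), bias=b,
                            selected_voxels=[list(np.flatnonzero(w))],
                            cv_accuracy=np.array([1.0]),
                            chosen_iteration=1, label_map=(0, 1))

    def test_zero_pattern_zero_bias(self):
        model = self._model([1.0, -2.0, 0.0])
        assert boundary_distance(model, np.zeros(3)) == 0.0

    def test_linear_in_scale(self):
        w = np.array([1.0, -2.0, 0.5])
        model = self._model(w)
        d1 = boundary_distance(model, w)
        d2 = boundary_distance(model, 2 * w)
        assert d1 > 0 and d2 == pytest.approx(2 * d1)

    def test_wrong_length_rejected(self):
        model = self._model([1.0, 1.0])
        with pytest.raises(ValueError):
            boundary_distance(model, np.zeros(3))

    def test_distance_tracks_confidence_on_coupled_patterns(self):
        # generator contract: patterns carrying graded confidence signal
        # yield boundary distances that rank-correlate with confidence
        from latentrl.behavior import spearman_rho
        rng = np.random.default_rng(5)
        conf = rng.integers(1, 5, 300)
        level = (conf - 2.5) / 1.5
        X = rng.standard_normal((300, 80))
        X[:, :20] += 1.2 * level[:, None]
        model = train_slr(X, conf >= 3, n_iterations=2, seed=6)
        dist = model.decision(X)
        assert spearman_rho(dist, conf) > 0.3


class TestStateLikelihood:
    def _model(self):
        w = np.zeros(5)
        w[0] = 1.0
        return DecoderModel(weights=w, bias=0.0, selected_voxels=[[0]],
                            cv_accuracy=np.array([1.0]),
                            chosen_iteration=1, label_map=(0, 1))

    def test_identical_trs_equal_single(self):
        model = self._model()
        tr = np.zeros((3, 5))
        tr[:, 0] = 0.7
        single = model.predict_proba(tr[:1])[0]
        assert state_likelihood(model, tr) == pytest.approx(single)

    def test_mean_of_three(self):
        model = self._model()
        logits = [np.log(p / (1 - p)) for p in (0.2, 0.5, 0.8)]
        tr = np.zeros((3, 5))
        tr[:, 0] = logits
        assert state_likelihood(model, tr) == pytest.approx(0.5, abs=1e-9)

    def test_wrong_tr_count_rejected(self):
        with pytest.raises(ValueError):
            state_likelihood(self._model(), np.zeros((2, 5)))


class TestChi2:
    def test_perfect_association_equals_n(self):
        a = np.arange(200) % 2 == 0
        assert chi2_2x2(a, a) == pytest.approx(200.0)
        assert chi2_2x2(a, ~a) == pytest.approx(200.0)

    def test_hand_computed_table(self):
        a = np.repeat([False, False, True, True], [30, 10, 10, 30])
        b = np.repeat([False, True, False, True], [30, 10, 10, 30])
        assert chi2_2x2(a, b) == pytest.approx(20.0)

    def test_empty_margin_convention(self):
        a = np.ones(50, dtype=bool)
        b = np.arange(50) % 2 == 0
        assert chi2_2x2(a, b) == 0.0

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        a = rng.random(100) < 0.5
        b = rng.random(100) < 0.5
        assert chi2_2x2(a, b) == pytest.approx(chi2_2x2(~a, ~b))


class TestAssociationPipeline:
    def test_window_layout(self):
        assert len(CONF_WINDOWS) == 9
        flat = {tr for w in CONF_WINDOWS for tr in w}
        assert flat == set(range(7, 17))
        assert all(1 <= len(w) <= 3 for w in CONF_WINDOWS)

    def _subject(self, seed, coupling, n_trials=80, n_vox=30):
        """Tiny subject whose decoders are hand-built identity readers of
        one voxel, with controllable anti-alignment of the two signals."""
        rng = np.random.default_rng(seed)
        conf_sig = rng.standard_normal(n_trials)
        rpe_sig = (1 - coupling) * rng.standard_normal(n_trials) \
            - coupling * conf_sig
        conf_trs = rng.standard_normal((n_trials, 22, n_vox)) * 0.2
        conf_trs[:, 6:16, 0] += conf_sig[:, None]
        rpe_pat = rng.standard_normal((n_trials, 2, n_vox)) * 0.2
        rpe_pat[:, :, 0] += rpe_sig[:, None]
        w = np.zeros(n_vox)
        w[0] = 3.0
        reader = dict(weights=w, bias=0.0, selected_voxels=[[0]],
                      cv_accuracy=np.array([1.0]), chosen_iteration=1,
                      label_map=(0, 1))
        return SubjectAssociationData(
            conf_model=DecoderModel(**reader),
            rpe_model=DecoderModel(**reader),
            conf_trs=conf_trs, rpe_patterns=rpe_pat)

    def test_bootstrap_reproducible_from_seed(self):
        subs = [self._subject(s, 0.5) for s in range(3)]
        a = chi2_association(subs, n_boot=30, seed=9)
        b = chi2_association(subs, n_boot=30, seed=9)
        np.testing.assert_array_equal(a.chi2_distribution,
                                      b.chi2_distribution)
        np.testing.assert_array_equal(a.target_counts, b.target_counts)

    def test_counts_partition_trials(self):
        subs = [self._subject(s, 0.3) for s in range(3)]
        res = chi2_association(subs, n_boot=20, seed=10)
        total = sum(len(s.rpe_patterns) for s in subs)
        assert ((res.target_counts + res.opposite_counts) == total).all()

    def test_coupling_raises_association_and_target_excess(self):
        null = [self._subject(s, 0.0) for s in range(4)]
        coupled = [self._subject(s, 0.9) for s in range(4)]
        r0 = chi2_association(null, n_boot=60, seed=11)
        r1 = chi2_association(coupled, n_boot=60, seed=11)
        assert r1.chi2_distribution.mean() > r0.chi2_distribution.mean()
        assert (r1.target_counts.mean() - r1.opposite_counts.mean()
                > r0.target_counts.mean() - r0.opposite_counts.mean())
        assert r1.target_counts.mean() > r1.opposite_counts.mean()
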