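"""BNN training, SVM calibration, and the three-stage fusion classifier."""

import warnings

import numpy as np
import pytest

from octdr.fusion import (MARKERS, CalibratedLinearSVM, Diagnosis,
                          FusionConfig, FusionModel, render_layer_map)
from octdr.nnet import BNN, BNNParams


class TestBNN:
    def test_xor_capacity(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float)
        y = np.array([0, 1, 1, 0])
        ok = False
        for seed in range(5):
            net = BNN(2, 2, 2, params=BNNParams(max_epochs=5000,
                                                learning_rate=0.1,
                                                patience=5000), seed=seed)
            net.fit(X, y)
            if np.array_equal(net.predict(X), y):
                ok = True
                break
        assert ok

    def test_analytic_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        net = BNN(3, 4, 2, seed=1)
        X = rng.normal(size=(7, 3))
        y = rng.integers(0, 2, 7)
        T = np.zeros((7, 2))
        T[np.arange(7), y] = 1.0
        grads = net.gradients(X, T)
        eps = 1e-6
        for wname, g in zip(("W1", "b1", "W2", "b2"), grads):
            w = getattr(net, wname)
            it = np.nditer(w, flags=["multi_index"])
            for _ in range(min(w.size, 10)):
                ix = it.multi_index
                orig = w[ix]
                w[ix] = orig + eps
                lp = net.loss(X, T)
                w[ix] = orig - eps
                lm = net.loss(X, T)
                w[ix] = orig
                fd = (lp - lm) / (2 * eps)
                assert g[ix] == pytest.approx(fd, rel=1e-5, abs=1e-8)
                it.iternext()

    def test_softmax_rows_sum_to_one(self):
        net = BNN(4, 49, 2, seed=0)
        p = net.predict_proba(np.random.default_rng(1).normal(size=(5, 4)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((p >= 0) & (p <= 1))

    def test_training_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 4))
        y = (X[:, 0] > 0).astype(int)
        a = BNN(4, 8, seed=3).fit(X, y)
        b = BNN(4, 8, seed=3).fit(X, y)
        assert np.array_equal(a.W1, b.W1) and np.array_equal(a.W2, b.W2)

    def test_nonfinite_input_rejected(self):
        net = BNN(2, 3)
        with pytest.raises(ValueError, match="finite"):
            net.fit(np.array([[1.0, np.nan]]), np.array([0]))

    def test_state_roundtrip(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 3))
        y = (X.sum(axis=1) > 0).astype(int)
        net = BNN(3, 5, seed=0).fit(X, y)
        clone = BNN.from_state(net.state_dict())
        np.testing.assert_array_equal(net.predict_proba(X),
                                      clone.predict_proba(X))


class TestCalibratedSVM:
    def test_separable_training_accuracy(self):
        X = np.concatenate([np.full((10, 1), -2.0), np.full((10, 1), 2.0)])
        y = np.array([0] * 10 + [1] * 10)
        clf = CalibratedLinearSVM().fit(X, y)
        p = clf.predict_proba(X)
        assert np.all((p[:10] < 0.5) & (p[10:] > 0.5))

    def test_probabilities_monotone_in_decision_value(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        y = (X[:, 0] + 0.3 * rng.normal(size=40) > 0).astype(int)
        clf = CalibratedLinearSVM().fit(X, y)
        d = clf.decision_function(X)
        p = clf.predict_proba(X)
        order = np.argsort(d)
        assert np.all(np.diff(p[order]) >= -1e-12)
        assert np.all((p >= 0) & (p <= 1))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            CalibratedLinearSVM().fit(np.zeros((5, 2)), np.zeros(5))

    def test_label_permutation_gives_chance_auc(self):
        """Out-of-fold stacking under the permutation null: AUC ~ 0.5."""
        from sklearn.metrics import roc_auc_score
        from octdr.fusion import _oof_decision_values

        rng = np.random.default_rng(1)
        aucs = []
        for rep in range(20):
            X = rng.normal(size=(60, 5))
            y = rng.permutation([0] * 30 + [1] * 30)
            groups = np.repeat(np.arange(30), 2)
            d = _oof_decision_values(X, y, groups)
            aucs.append(roc_auc_score(y, d))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)


@pytest.fixture(scope="module")
def trained(small_cohort_features):
    _, manifest, feats = small_cohort_features
    model = FusionModel(FusionConfig(seed=0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(feats)
    return model, feats


class TestFusionModel:
    def test_training_resubstitution_sane(self, trained):
        model, feats = trained
        diags = model.predict(feats)
        truth = [f.class_label for f in feats]
        acc = np.mean([d.predicted_class == t
                       for d, t in zip(diags, truth)])
        assert acc >= 0.9

    def test_probabilities_valid_and_sum_to_one(self, trained):
        model, feats = trained
        d = model.predict(feats[:4])
        for diag in d:
            assert 0.0 <= diag.global_probability <= 1.0
            assert np.all((diag.layer_probabilities >= 0)
                          & (diag.layer_probabilities <= 1))
        # softmax pair sums to 1 by construction
        p = model.global_net.predict_proba(
            d[0].layer_probabilities.reshape(1, -1))
        assert p.sum() == pytest.approx(1.0)

    def test_fuse_layer_behaviour(self, trained):
        model, _ = trained
        confident = model.fuse_layer(0, np.ones((1, 4)))[0]
        neutral = model.fuse_layer(0, np.full((1, 4), 0.5))[0]
        assert confident > 0.9
        assert 0.05 < neutral < 0.95
        # marker order matters: permuting inputs changes the output
        rng = np.random.default_rng(0)
        x = rng.uniform(0.1, 0.9, (1, 4))
        assert model.fuse_layer(0, x)[0] != pytest.approx(
            model.fuse_layer(0, x[:, ::-1])[0], abs=1e-9)

    def test_fuse_layer_imputes_missing_with_half(self, trained):
        model, _ = trained
        x = np.array([[0.8, np.nan, 0.8, 0.8]])
        with pytest.warns(UserWarning, match="0.5"):
            out = model.fuse_layer(0, x)
        ref = model.fuse_layer(0, np.array([[0.8, 0.5, 0.8, 0.8]]))
        assert out[0] == pytest.approx(ref[0])

    def test_fuse_global_contract(self, trained):
        model, _ = trained
        d = model.fuse_global(np.ones(12))
        assert d.predicted_class == "DR"
        assert d.global_probability > 0.9
        with pytest.raises(ValueError, match="12"):
            model.fuse_global(np.ones(5))
        # repeat predictions identical (no predict-time randomness)
        d2 = model.fuse_global(np.ones(12))
        assert d2.global_probability == d.global_probability

    def test_single_class_training_rejected(self, small_cohort_features):
        _, _, feats = small_cohort_features
        dr_only = [f for f in feats if f.class_label == "DR"]
        with pytest.raises(ValueError, match="single-class"):
            FusionModel().fit(dr_only)

    def test_save_load_roundtrip(self, trained, tmp_path):
        model, feats = trained
        model.save(tmp_path / "model")
        assert (tmp_path / "model" / "architecture.json").exists()
        clone = FusionModel.load(tmp_path / "model")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = model.predict(feats[:3])
            b = clone.predict(feats[:3])
        for x, y in zip(a, b):
            assert x.global_probability == pytest.approx(
                y.global_probability, abs=1e-12)
            assert x.predicted_class == y.predicted_class

    def test_training_reproducible(self, small_cohort_features):
        _, _, feats = small_cohort_features
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = FusionModel(FusionConfig(seed=5)).fit(feats)
            b = FusionModel(FusionConfig(seed=5)).fit(feats)
        np.testing.assert_array_equal(a.global_net.W1, b.global_net.W1)
        pa = a.predict(feats[:2])
        pb = b.predict(feats[:2])
        assert pa[0].global_probability == pb[0].global_probability


def test_dropping_reflectivity_hurts_most_when_it_dominates():
    """On a cohort whose only DR signal is reflectivity, removing the
    reflectivity marker degrades accuracy more than removing any other
    single marker."""
    from octdr.evaluation import run_experiment
    from octdr.fusion import extract_layer_features
    from octdr.phantom import DREffect, PhantomConfig, generate_cohort

    effect = DREffect(thickness_delta=(0.0,) * 12,
                      reflectivity_delta=(-18.0, -10.0, 0, 0, 0, -12.0,
                                          0, 0, 0, 0, 0, 0),
                      tortuosity_amplitude=0.0,
                      noise_scale_factor=1.0,
                      noise_correlation_length=0.0)
    cfg = PhantomConfig(seed=31, dr_effect=effect)
    scans, manifest = generate_cohort(cfg, 10, 0.5, 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        feats = [extract_layer_features(
            s.image, s.truth_labels, scan_id=f"s{i}",
            subject_id=s.subject_id, class_label=s.class_label)
            for i, s in enumerate(scans)]
        accs = {}
        for dropped in MARKERS:
            kept = tuple(m for m in MARKERS if m != dropped)
            rep = run_experiment(
                feats, manifest, schemes=("k2",),
                fusion_config=FusionConfig(seed=0, markers=kept))
            accs[dropped] = rep["schemes"]["k2"]["metrics"]["accuracy"]
    others = [accs[m] for m in MARKERS if m != "reflectivity"]
    assert accs["reflectivity"] < min(others)


class TestDiagnosisAndRendering:
    def test_diagnosis_rejects_invalid_probabilities(self):
        with pytest.raises(ValueError):
            Diagnosis(layer_probabilities=np.full(12, 1.5),
                      global_probability=0.5, predicted_class="DR")

    def test_render_layer_map_hue_scaling(self, noiseless_scan):
        probs = np.full(12, 0.5)
        probs[0] = 1.0   # saturated DR layer
        probs[1] = 0.0   # saturated normal layer
        rgb = render_layer_map(noiseless_scan.image,
                               noiseless_scan.truth_labels, probs)
        nfl = noiseless_scan.truth_labels == 1
        gcl = noiseless_scan.truth_labels == 2
        bg = noiseless_scan.truth_labels == 0
        # darkest red for p=1, lightest hue for p=0.5
        assert np.allclose(rgb[nfl][:, 0], 1.0)
        assert rgb[nfl][:, 1].max() < 0.3
        assert np.allclose(rgb[gcl][:, 2], 1.0)
        # probability exactly 0.5 -> lightest hue of the winning class
        ipl = noiseless_scan.truth_labels == 3
        assert np.allclose(rgb[ipl], 1.0)
        # background stays grayscale
        assert np.allclose(rgb[bg][:, 0], rgb[bg][:, 1])
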