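import numpy as np
import pytest

from splicekit import training_data as td
from splicekit.cnn_model import CnnConfig, CnnModel, train
from splicekit.formats_io import GenomeSequence
from splicekit.training_data import DatasetSplit, SpliceSite, SpliceSiteExample

SMALL = CnnConfig(window=30, conv_features=(4, 4), seed=0)


def _random_windows(n, width, seed=0):
    rng = np.random.default_rng(seed)
    w = np.zeros((n, 4, width), dtype=np.float32)
    idx = rng.integers(0, 4, size=(n, width))
    for i in range(n):
        w[i, idx[i], np.arange(width)] = 1.0
    return w


class TestForward:
    def test_untrained_model_scores_half(self):
        model = CnnModel(CnnConfig(seed=3))
        w = _random_windows(1, 202)[0]
        assert model.forward(w) == pytest.approx(0.5)

    def test_batch_equals_per_example(self):
        model = CnnModel(SMALL)
        rng = np.random.default_rng(1)
        model.params["wd"] = rng.standard_normal(model.params["wd"].shape)
        ws = _random_windows(7, 30, seed=2)
        batch = model.forward(ws)
        singles = np.array([model.forward(w) for w in ws])
        np.testing.assert_allclose(batch, singles, rtol=1e-12)

    def test_all_n_window_is_finite(self):
        model = CnnModel(SMALL)
        t = model.forward(np.zeros((4, 30)))
        assert 0.0 < t < 1.0

    def test_shape_mismatch_rejected(self):
        model = CnnModel(SMALL)
        with pytest.raises(ValueError, match="shape"):
            model.forward(np.zeros((4, 31)))

    def test_softmax_probabilities_sum_to_one(self):
        model = CnnModel(SMALL)
        rng = np.random.default_rng(0)
        for k in model.params:
            model.params[k] = rng.standard_normal(model.params[k].shape) * 0.3
        probs, _, _ = model._forward_full(_random_windows(5, 30).astype(np.float64))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-12)
        assert (probs >= 0).all()


class TestParameterCount:
    def test_conv_layer_arithmetic(self):
        # 16 filters x 4 channels x kernel 5, plus 16 biases
        model = CnnModel(CnnConfig())
        assert model.params["w1"].size + model.params["b1"].size == 16 * 4 * 5 + 16 == 336

    def test_dense_layer_arithmetic(self):
        cfg = CnnConfig(window=30, conv_features=(2, 5), seed=0)
        model = CnnModel(cfg)
        # dense head: n_classes x flat + n_classes
        assert model.params["wd"].size + model.params["bd"].size == 2 * cfg.flat_features + 2

    def test_default_total_is_stable(self):
        model = CnnModel(CnnConfig())
        analytic = (16 * 4 * 5 + 16) + (16 * 16 * 5 + 16) + (2 * 16 * 47 + 2)
        assert model.parameter_count() == analytic == 3138


def test_analytic_gradient_matches_finite_differences():
    """Backprop through conv/pool/dense checked against central differences."""
    model = CnnModel(CnnConfig(window=20, conv_features=(3, 3), seed=4))
    rng = np.random.default_rng(8)
    for k in model.params:
        model.params[k] = rng.standard_normal(model.params[k].shape) * 0.5
    X = _random_windows(6, 20, seed=9).astype(np.float64)
    y = np.array([0, 1, 0, 1, 1, 0])
    _, grads = model.loss_and_grad(X, y)
    eps = 1e-6
    for name in ("w1", "w2", "wd", "b1", "bd"):
        flat = model.params[name].ravel()
        for idx in rng.choice(flat.size, size=min(5, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            lp, _ = model.loss_and_grad(X, y)
            flat[idx] = orig - eps
            lm, _ = model.loss_and_grad(X, y)
            flat[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            analytic = grads[name].ravel()[idx]
            assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-7)


def _toy_split(n=160, width=30, seed=0):
    """Linearly separable windows: planted AAAA motif vs uniform background."""
    rng = np.random.default_rng(seed)
    examples = []
    for i in range(n):
        label = i % 2
        w = _random_windows(1, width, seed=int(rng.integers(1 << 30)))[0]
        if label:
            w[:, 5:11] = 0.0
            w[0, 5:11] = 1.0
        chrom = "c1"
        site = SpliceSite(chrom, i, "+", td.DONOR, label, f"g{i}")
        examples.append(SpliceSiteExample(site, w))
    k = int(n * 0.8)
    return DatasetSplit(examples[:k], examples[k:], ["c2"])


class TestTraining:
    def test_fits_linearly_separable_toy_data(self):
        split = _toy_split()
        model = CnnModel(CnnConfig(window=30, conv_features=(8, 8), seed=0))
        train(model, split, lr=5e-3, max_epochs=20, patience=20, seed=0)
        X, y = td.stack_windows(split.train)
        acc = ((model.forward(X) > 0.5).astype(int) == y).mean()
        assert acc >= 0.99

    def test_early_stopping_restores_best_weights(self):
        split = _toy_split(n=60)
        model = CnnModel(CnnConfig(window=30, conv_features=(4, 4), seed=1))
        state = train(model, split, max_epochs=50, patience=3, seed=1)
        assert state.best_val_cost == min(state.val_cost)
        if state.stopped_early:
            # stopped exactly `patience` epochs after the best one
            assert state.epoch == state.best_epoch + 1 + 3
        # restored weights reproduce the best validation cost
        Xv, yv = td.stack_windows(split.validation)
        probs = np.stack([1 - model.forward(Xv), model.forward(Xv)], axis=1)
        cost = -np.log(np.clip(probs[np.arange(len(yv)), yv], 1e-12, None)).mean()
        assert cost == pytest.approx(state.best_val_cost, rel=1e-9)

    def test_same_seed_same_weights(self):
        split = _toy_split(n=60)
        models = []
        for _ in range(2):
            m = CnnModel(CnnConfig(window=30, conv_features=(4, 4), seed=2))
            train(m, split, max_epochs=5, patience=5, seed=2)
            models.append(m)
        for k in models[0].params:
            np.testing.assert_array_equal(models[0].params[k], models[1].params[k])

    def test_empty_validation_rejected(self):
        split = _toy_split(n=20)
        split.validation = []
        with pytest.raises(ValueError, match="non-empty"):
            train(CnnModel(CnnConfig(window=30, conv_features=(4, 4))), split)


class TestActivations:
    def test_identical_sets_give_zero_diff(self):
        model = CnnModel(SMALL)
        w = _random_windows(5, 30)
        diff = model.activation_rate_diff(w, w)
        np.testing.assert_array_equal(diff, 0.0)

    def test_diff_bounded_by_one(self):
        model = CnnModel(SMALL)
        rng = np.random.default_rng(2)
        for k in ("w1", "w2"):
            model.params[k] = rng.standard_normal(model.params[k].shape)
        diff = model.activation_rate_diff(
            _random_windows(20, 30, 1), _random_windows(20, 30, 2)
        )
        assert np.abs(diff).max() <= 1.0

    def test_boundary_cells_more_discriminative_than_edges(self, default_pipeline):
        """Controlled contrast: negatives share the positives' flanks but have
        the central splice signal destroyed (columns shuffled), so activation
        differences must concentrate near the boundary, not at window edges."""
        res = default_pipeline
        genome = res.sim.genome_dict
        pos = [s for s in res.sim.truth_sites if s.site_type == td.DONOR][:150]
        Xp, _ = td.stack_windows(td.build_examples(pos, genome)[0])
        rng = np.random.default_rng(0)
        Xn = Xp.copy()
        w = Xp.shape[2]
        for i in range(len(Xn)):
            cols = np.arange(w // 2 - 10, w // 2 + 10)
            Xn[i][:, cols] = Xn[i][:, rng.permutation(cols)]
        diff = np.abs(res.model.activation_rate_diff(Xp, Xn))
        n = diff.shape[1]
        center = diff[:, n // 2 - 5 : n // 2 + 5].mean()
        edges = np.concatenate([diff[:, :5], diff[:, -5:]], axis=1).mean()
        assert center > edges

    def test_embed_matches_internal_activations(self):
        model = CnnModel(SMALL)
        rng = np.random.default_rng(6)
        for k in ("w1", "w2"):
            model.params[k] = rng.standard_normal(model.params[k].shape)
        w = _random_windows(3, 30, 7)
        emb = model.embed(w)
        assert emb.shape[0] == 3
        np.testing.assert_array_equal(
            emb, model.last_pool_activations(w).reshape(3, -1)
        )
        np.testing.assert_array_equal(emb, model.embed(w))  # deterministic
        assert model.embed(w[0]).shape[0] == 1


def test_checkpoint_roundtrip(tmp_path):
    from splicekit.calibration import CalibrationTable

    model = CnnModel(CnnConfig(window=30, conv_features=(4, 4), seed=5))
    rng = np.random.default_rng(0)
    for k in model.params:
        model.params[k] = rng.standard_normal(model.params[k].shape)
    table = CalibrationTable(
        b=10, P=np.arange(10, dtype=np.int64), N=np.arange(10, dtype=np.int64)[::-1].copy()
    )
    path = tmp_path / "model.skm.npz"
    model.save(path, calibration=table)
    loaded, table2 = CnnModel.load(path)
    assert loaded.config == model.config
    for k in model.params:
        np.testing.assert_array_equal(loaded.params[k], model.params[k])
    np.testing.assert_array_equal(table2.P, table.P)
    np.testing.assert_array_equal(table2.N, table.N)
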