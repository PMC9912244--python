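"""Architecture, training and prediction contracts of the CRNN."""

from __future__ import annotations

import numpy as np
import pytest

from cas13guide.deep_model import (
    DeepGuideScorer,
    ModelConfig,
    build_crnn,
    fit,
    load_model,
    predict_deep_score,
    save_model,
    tune_grid,
)
from cas13guide.encoding import lfc_to_target

SMALL = dict(conv_filters=8, dense_units=16, recurrent_units=8)


def _random_batch(rng, n, L=30):
    seq = rng.random((n, L, 4))
    struct = rng.random((n, L, 3))
    mask = np.ones((n, L))
    return seq, struct, mask


class TestArchitecture:
    def test_forward_bounded(self):
        rng = np.random.default_rng(0)
        model = build_crnn(ModelConfig(**SMALL), L=30)
        model.trained = True
        seq, struct, mask = _random_batch(rng, 16)
        out = predict_deep_score(model, seq, struct, mask)
        assert np.all((out >= 0) & (out <= 1))

    def test_two_conv_layers_per_branch(self):
        summary = build_crnn(ModelConfig(**SMALL)).architecture_summary()
        assert summary["branches"]["sequence"]["conv_layers"] == 2
        assert summary["branches"]["structure"]["conv_layers"] == 2
        assert summary["output"] == "sigmoid"

    def test_doubling_dense_units_increases_parameters(self):
        small = build_crnn(ModelConfig(**SMALL)).n_parameters()
        big = build_crnn(ModelConfig(**{**SMALL, "dense_units": 32})).n_parameters()
        assert big > small

    def test_default_dropout_rates(self):
        cfg = ModelConfig()
        assert cfg.dropout_conv == 0.5
        assert cfg.dropout_lstm == 0.3

    def test_kernel_larger_than_input_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            build_crnn(ModelConfig(conv_kernel=40), L=30)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(dropout_conv=1.0)
        with pytest.raises(ValueError):
            ModelConfig(optimizer="nadamw")


class TestTraining:
    def test_memorizes_tiny_dataset(self):
        rng = np.random.default_rng(3)
        seq, struct, mask = _random_batch(rng, 20)
        y = rng.uniform(0.1, 0.9, 20)
        cfg = ModelConfig(**SMALL, epochs=500, batch_size=20, dropout_conv=0.0,
                          dropout_lstm=0.0, seed=0)
        model = build_crnn(cfg)
        history = fit(model, seq, struct, mask, y, cfg)
        assert history[-1] < 0.01

    def test_learns_planted_signal(self, planted_dataset, small_trained_model):
        seq, struct, mask = planted_dataset["arrays"]
        targets = lfc_to_target(planted_dataset["lfc"])
        pred = predict_deep_score(small_trained_model, seq, struct, mask)
        # training reduced the loss
        first = np.mean((pred - targets) ** 2)
        assert first < np.var(targets)
        # top-efficiency decile scores higher than bottom decile
        eff = planted_dataset["efficiency"]
        order = np.argsort(eff)
        assert pred[order[-50:]].mean() > pred[order[:50]].mean()

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(4)
        seq, struct, mask = _random_batch(rng, 40)
        y = rng.uniform(0, 1, 40)
        cfg = ModelConfig(**SMALL, epochs=3, seed=11)
        preds = []
        for _ in range(2):
            m = build_crnn(cfg)
            fit(m, seq, struct, mask, y, cfg)
            preds.append(predict_deep_score(m, seq, struct, mask))
        np.testing.assert_allclose(preds[0], preds[1], atol=1e-3)

    def test_non_finite_loss_aborts_with_diagnostics(self):
        rng = np.random.default_rng(5)
        seq, struct, mask = _random_batch(rng, 120)
        y = rng.uniform(0, 1, 120)
        y[3] = np.nan  # poisoned target makes the loss non-finite
        cfg = ModelConfig(**SMALL, epochs=2, seed=0)
        model = build_crnn(cfg)
        with pytest.raises(RuntimeError, match="loss"):
            fit(model, seq, struct, mask, y, cfg)

    def test_structure_branch_carries_structure_signal(self):
        """On data whose efficiency depends only on folding, dropping the
        structure branch costs cross-validated AUC."""
        from sklearn.metrics import roc_auc_score

        from cas13guide.encoding import encode_guide
        from cas13guide.evaluation import kfold_predictions
        from cas13guide.simulate import planted_efficiency
        from cas13guide.structure import fold_mfe

        rng = np.random.default_rng(17)
        alphabet = np.array(list("ACGU"))
        spacers = ["".join(rng.choice(alphabet, 22)) for _ in range(500)]
        folds = [fold_mfe(s, engine="maxpair") for s in spacers]
        eff = np.array([planted_efficiency(s, f, weights=(0.0, 4.0, 0.0))
                        for s, f in zip(spacers, folds)])
        lfc = -2.0 * eff + rng.normal(0, 0.2, 500)
        enc = [encode_guide(s, f, 30) for s, f in zip(spacers, folds)]
        labels = (lfc <= -0.5).astype(int)
        aucs = {}
        for use_structure in (True, False):
            est = DeepGuideScorer(conv_filters=16, dense_units=32,
                                  recurrent_units=32, epochs=15, seed=0,
                                  use_structure=use_structure)
            pred = kfold_predictions(est, enc, lfc, k=3, seed=1)
            aucs[use_structure] = roc_auc_score(labels, pred)
        assert aucs[True] > aucs[False]

    def test_small_dataset_warns(self):
        rng = np.random.default_rng(6)
        seq, struct, mask = _random_batch(rng, 20)
        cfg = ModelConfig(**SMALL, epochs=1, seed=0)
        with pytest.warns(UserWarning, match="training pairs"):
            fit(build_crnn(cfg), seq, struct, mask, rng.uniform(0, 1, 20), cfg)


class TestPrediction:
    def test_untrained_model_rejected(self):
        rng = np.random.default_rng(0)
        model = build_crnn(ModelConfig(**SMALL))
        with pytest.raises(RuntimeError, match="untrained"):
            predict_deep_score(model, *_random_batch(rng, 4))

    def test_batch_order_invariance(self, planted_dataset, small_trained_model):
        seq, struct, mask = planted_dataset["arrays"]
        pred = predict_deep_score(small_trained_model, seq, struct, mask)
        perm = np.random.default_rng(1).permutation(len(seq))
        pred_perm = predict_deep_score(small_trained_model, seq[perm], struct[perm], mask[perm])
        np.testing.assert_allclose(pred_perm, pred[perm], atol=1e-6)

    def test_batched_equals_single(self, planted_dataset, small_trained_model):
        seq, struct, mask = planted_dataset["arrays"]
        batched = predict_deep_score(small_trained_model, seq[:8], struct[:8], mask[:8])
        singles = np.concatenate([
            predict_deep_score(small_trained_model, seq[i:i+1], struct[i:i+1], mask[i:i+1])
            for i in range(8)
        ])
        np.testing.assert_allclose(batched, singles, atol=1e-6)

    def test_save_load_roundtrip(self, planted_dataset, small_trained_model, tmp_path):
        seq, struct, mask = planted_dataset["arrays"]
        prefix = str(tmp_path / "model")
        save_model(small_trained_model, prefix)
        restored = load_model(prefix)
        np.testing.assert_array_equal(
            predict_deep_score(restored, seq[:16], struct[:16], mask[:16]),
            predict_deep_score(small_trained_model, seq[:16], struct[:16], mask[:16]),
        )


class TestGridSearch:
    def _data(self):
        rng = np.random.default_rng(7)
        seq = rng.random((60, 12, 4))
        struct = rng.random((60, 12, 3))
        mask = np.ones((60, 12))
        y = 0.2 + 0.6 * seq[:, :, 1].mean(axis=1)
        return seq, struct, mask, y

    def test_cartesian_product_rows(self):
        seq, struct, mask, y = self._data()
        base = ModelConfig(**SMALL, epochs=2)
        _, table = tune_grid({"dense_units": [8, 16], "learning_rate": [1e-3, 1e-2]},
                             seq, struct, mask, y, seed=0, base_config=base)
        assert len(table) == 4

    def test_degenerate_learning_rate_ranks_last(self):
        seq, struct, mask, y = self._data()
        base = ModelConfig(**SMALL, epochs=10)
        best, table = tune_grid({"learning_rate": [1e-3, 10.0]},
                                seq, struct, mask, y, seed=0, base_config=base)
        assert best.learning_rate == 1e-3
        mse = table.set_index("learning_rate")["val_mse"]
        assert mse[1e-3] < mse[10.0]

    def test_rerun_same_seed_same_selection(self):
        seq, struct, mask, y = self._data()
        base = ModelConfig(**SMALL, epochs=2)
        grid = {"dense_units": [8, 16]}
        b1, _ = tune_grid(grid, seq, struct, mask, y, seed=3, base_config=base)
        b2, _ = tune_grid(grid, seq, struct, mask, y, seed=3, base_config=base)
        assert b1 == b2

    def test_empty_grid_rejected(self):
        seq, struct, mask, y = self._data()
        with pytest.raises(ValueError):
            tune_grid({}, seq, struct, mask, y)
        with pytest.raises(ValueError):
            tune_grid({"dense_units": []}, seq, struct, mask, y)


class TestEstimator:
    def test_sklearn_params_roundtrip(self):
        est = DeepGuideScorer(epochs=2, dense_units=16)
        params = est.get_params()
        assert params["epochs"] == 2
        est2 = DeepGuideScorer(**params)
        assert est2.get_params() == params

    def test_fit_predict_on_spacers(self, planted_dataset):
        est = DeepGuideScorer(**SMALL, epochs=3, engine="maxpair", seed=0)
        spacers = planted_dataset["spacers"][:120]
        lfcs = planted_dataset["lfc"][:120]
        est.fit(spacers, lfcs)
        scores = est.predict(spacers[:10])
        assert scores.shape == (10,)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_unfitted_predict_rejected(self):
        with pytest.raises(RuntimeError):
            DeepGuideScorer().predict(["ACGU"])
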