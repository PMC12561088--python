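"""Fusion classifier: pair assembly, architecture, two-stage training."""

import numpy as np
import pytest

from ddifuse import (
    DDIPair,
    FeatureStore,
    FusionMLP,
    ModelConfig,
    assemble_pair_vector,
    fine_tune_stage2,
    train_stage1,
)


@pytest.fixture()
def full_scale_store(rng):
    """A store with the full-scale modality dimensions (200/300/768)."""
    store = FeatureStore(["A", "B", "C"])
    store.add("ssp", rng.standard_normal((3, 200)))
    store.add("psp", rng.standard_normal((3, 300)))
    store.add("emb", rng.standard_normal((3, 768)))
    return store


def toy_problem(rng, n=200, dim=10, n_classes=2):
    """Linearly separable two-blob data."""
    y = rng.integers(n_classes, size=n)
    centers = rng.standard_normal((n_classes, dim)) * 4
    X = centers[y] + 0.3 * rng.standard_normal((n, dim))
    return X, y


def toy_config(**kw):
    defaults = dict(
        modalities=("ssp",), input_dim=10, hidden_dim=16, n_classes=2,
        dropout=0.0, batch_size=32, max_epochs_stage1=15, early_stop_after=15,
        max_epochs_stage2=10, seed=0,
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestAssembly:
    def test_pair_vector_lengths(self, full_scale_store):
        pair = DDIPair("A", "B", 0)
        assert assemble_pair_vector(pair, full_scale_store, ("ssp", "emb")).shape == (1936,)
        assert assemble_pair_vector(pair, full_scale_store, ("emb",)).shape == (1536,)
        assert assemble_pair_vector(pair, full_scale_store, ("ssp", "psp", "emb")).shape == (2536,)

    def test_order_sensitive(self, full_scale_store):
        ab = assemble_pair_vector(DDIPair("A", "B", 0), full_scale_store, ("ssp",))
        ba = assemble_pair_vector(DDIPair("B", "A", 0), full_scale_store, ("ssp",))
        assert not np.array_equal(ab, ba)
        assert np.array_equal(ab[:200], ba[200:])  # drug-major blocks swap

    def test_missing_drug_or_modality_named(self, full_scale_store):
        with pytest.raises(KeyError, match="ZZ"):
            assemble_pair_vector(DDIPair("ZZ", "B", 0), full_scale_store, ("ssp",))
        with pytest.raises(KeyError, match="nope"):
            assemble_pair_vector(DDIPair("A", "B", 0), full_scale_store, ("nope",))


class TestArchitecture:
    def test_projection_parameter_count(self):
        with_proj = FusionMLP(toy_config(use_projection=True, input_dim=37))
        without = FusionMLP(toy_config(use_projection=False, input_dim=37))
        assert with_proj.n_parameters - without.n_parameters == 37**2 + 37

    def test_forward_shape(self, rng):
        model = FusionMLP(toy_config(n_classes=79, input_dim=20))
        proba = model.predict_proba(rng.standard_normal((7, 20)))
        assert proba.shape == (7, 79)

    def test_seeded_init_identical(self):
        m1 = FusionMLP(toy_config(seed=11))
        m2 = FusionMLP(toy_config(seed=11))
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            FusionMLP(toy_config(hidden_dim=0))
        with pytest.raises(ValueError):
            ModelConfig(n_classes=1)


class TestPredictProba:
    def test_rows_sum_to_one(self, rng):
        model = FusionMLP(toy_config(n_classes=5, input_dim=8))
        proba = model.predict_proba(rng.standard_normal((20, 8)))
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(proba >= 0)

    def test_identical_rows_identical_outputs(self, rng):
        model = FusionMLP(toy_config(input_dim=8, dropout=0.5))  # eval mode: no dropout
        x = rng.standard_normal(8)
        proba = model.predict_proba(np.stack([x, x]))
        assert np.array_equal(proba[0], proba[1])

    def test_zero_logits_give_uniform(self):
        model = FusionMLP(toy_config(n_classes=79, input_dim=8))
        model.params["Wo"][:] = 0.0
        model.params["bo"][:] = 0.0
        proba = model.predict_proba(np.zeros((1, 8)))
        assert np.allclose(proba, 1 / 79, atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        model = FusionMLP(toy_config(input_dim=8))
        with pytest.raises(ValueError):
            model.predict_proba(rng.standard_normal((3, 9)))


class TestStage1:
    def test_loss_drops_on_separable_data(self, rng):
        X, y = toy_problem(rng)
        cfg = toy_config()
        model = FusionMLP(cfg)
        hist = train_stage1(model, X, y, X, y, cfg)
        assert hist.records[9].train_loss < hist.records[0].train_loss
        assert hist.best_val_accuracy > 0.9

    def test_bit_identical_across_runs(self, rng):
        X, y = toy_problem(rng)
        cfg = toy_config(dropout=0.3, max_epochs_stage1=5, early_stop_after=5)
        h1 = train_stage1(FusionMLP(cfg), X, y, X, y, cfg)
        h2 = train_stage1(FusionMLP(cfg), X, y, X, y, cfg)
        assert [(r.train_loss, r.val_accuracy) for r in h1.records] == [
            (r.train_loss, r.val_accuracy) for r in h2.records
        ]
        for k in h1.best_state:
            assert np.array_equal(h1.best_state[k], h2.best_state[k])

    def test_early_stop_patience_arithmetic(self, rng):
        """No improvement past the activation epoch: stop exactly patience later."""
        X, y = toy_problem(rng, n=40)
        cfg = toy_config(max_epochs_stage1=300, early_stop_after=200, seed=2)
        calls = iter(range(10**6))

        def stub_metric(model, Xv, yv):
            # improves until epoch 200, frozen afterwards
            return min(next(calls), 199) / 1000.0

        hist = train_stage1(FusionMLP(cfg), X[:8], y[:8], X, y, cfg,
                            val_metric_fn=stub_metric)
        assert hist.stopped_early
        assert hist.records[-1].epoch == 220

    def test_best_checkpoint_tracks_max(self, rng):
        X, y = toy_problem(rng, n=40)
        cfg = toy_config(max_epochs_stage1=10, early_stop_after=10)
        seq = iter([0.1, 0.5, 0.3, 0.9, 0.2, 0.1, 0.1, 0.1, 0.1, 0.1])

        def stub(model, Xv, yv):
            return next(seq)

        hist = train_stage1(FusionMLP(cfg), X[:8], y[:8], X, y, cfg, val_metric_fn=stub)
        assert hist.best_val_accuracy == 0.9
        assert hist.best_epoch == 4

    def test_divergent_loss_raises(self, rng):
        X, y = toy_problem(rng, n=64)
        cfg = toy_config(learning_rate=1e200, max_epochs_stage1=50, early_stop_after=50)
        with np.errstate(all="ignore"):
            with pytest.raises(FloatingPointError):
                train_stage1(FusionMLP(cfg), X, y, X, y, cfg)

    def test_empty_partition_rejected(self, rng):
        X, y = toy_problem(rng, n=10)
        cfg = toy_config()
        with pytest.raises(ValueError):
            train_stage1(FusionMLP(cfg), X[:0], y[:0], X, y, cfg)


class TestStage2:
    def _trained(self, rng, **cfg_kw):
        X, y = toy_problem(rng, n=40)
        cfg = toy_config(**cfg_kw)
        model = FusionMLP(cfg)
        h1 = train_stage1(model, X, y, X, y, cfg)
        return model, h1, X, y, cfg

    def test_plateau_decay_points(self, rng):
        """Never-improving validation from lr 1e-3: 1e-4 after epoch 5, 1e-5 after 10."""
        model, h1, X, y, cfg = self._trained(rng, max_epochs_stage2=30)
        h2 = fine_tune_stage2(h1.best_state, model, X, y, X, y, cfg,
                              val_metric_fn=lambda *_: 0.0)
        lr_by_epoch = {r.epoch: r.lr for r in h2.records}
        assert lr_by_epoch[5] == pytest.approx(1e-3)   # decay applies after epoch 5
        assert lr_by_epoch[6] == pytest.approx(1e-4)
        assert lr_by_epoch[10] == pytest.approx(1e-4)
        assert lr_by_epoch[11] == pytest.approx(1e-5)

    def test_lr_floor(self, rng):
        model, h1, X, y, cfg = self._trained(rng, max_epochs_stage2=100, patience=100)
        h2 = fine_tune_stage2(h1.best_state, model, X, y, X, y, cfg,
                              val_metric_fn=lambda *_: 0.0)
        assert all(r.lr >= 1e-6 for r in h2.records)
        assert h2.records[-1].lr == 1e-6

    def test_improving_metric_keeps_lr(self, rng):
        model, h1, X, y, cfg = self._trained(rng, max_epochs_stage2=20)
        calls = iter(range(10**6))
        h2 = fine_tune_stage2(h1.best_state, model, X, y, X, y, cfg,
                              val_metric_fn=lambda *_: next(calls))
        assert all(r.lr == pytest.approx(cfg.learning_rate) for r in h2.records)
        assert not h2.stopped_early

    def test_early_stop_in_stage2(self, rng):
        model, h1, X, y, cfg = self._trained(rng, max_epochs_stage2=100, patience=20)
        h2 = fine_tune_stage2(h1.best_state, model, X, y, X, y, cfg,
                              val_metric_fn=lambda *_: 0.0)
        assert h2.stopped_early and h2.records[-1].epoch == 20

    def test_missing_checkpoint_rejected(self, rng):
        model, h1, X, y, cfg = self._trained(rng)
        with pytest.raises(ValueError):
            fine_tune_stage2(None, model, X, y, X, y, cfg)

    def test_resume_restores_checkpoint_weights(self, rng):
        model, h1, X, y, cfg = self._trained(rng, max_epochs_stage2=1)
        fresh = FusionMLP(cfg)
        fine_tune_stage2(h1.best_state, fresh, X, y, X, y, cfg,
                         val_metric_fn=lambda *_: 1.0)  # epoch 1 improves, snapshot kept
        # the history baseline was evaluated on the restored checkpoint
        restored = FusionMLP(cfg)
        restored.load_state_dict(h1.best_state)
        assert np.array_equal(restored.params["Wh"], h1.best_state["Wh"])
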