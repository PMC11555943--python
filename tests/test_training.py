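"""Joint loss identity, schedule, determinism, and grid search."""

from dataclasses import replace

import numpy as np
import pytest

from adrfuse.autodiff import Tensor, parameter
from adrfuse.corpus import PairSample
from adrfuse.fusion import PairPrediction
from adrfuse.training import (
    DEFAULT_DROPOUT_GRID,
    DEFAULT_GAMMA_GRID,
    TrainingConfig,
    TrainingDivergence,
    inner_grid_search,
    joint_loss,
    learning_rate_at,
    load_params,
    matrix_from_samples,
    save_params,
    train_model,
    JointModel,
)


def _pred(as_vals, fs_vals):
    return PairPrediction(AS=Tensor(np.asarray(as_vals, float)), FS=Tensor(np.asarray(fs_vals, float)))


class TestJointLoss:
    def test_perfect_predictions_leave_only_regularizer(self):
        params = {"w": parameter(np.array([2.0, -1.0]))}
        pred = _pred([1.0, 0.0], [4.0, 0.0])
        total, bd = joint_loss(pred, np.array([1.0, 0.0]), np.array([4.0, 0.0]),
                               np.array([True, False]), params, gamma=0.01)
        assert bd.L1 == 0.0 and bd.L2 == 0.0
        assert float(total.data) == pytest.approx(0.01 * 5.0)

    def test_hand_computed_single_positive(self):
        pred = _pred([0.5], [3.0])
        total, bd = joint_loss(pred, np.array([1.0]), np.array([5.0]), np.array([True]),
                               {}, gamma=0.0)
        assert bd.L1 == pytest.approx(0.25)
        assert bd.L2 == pytest.approx(4.0)
        assert float(total.data) == pytest.approx(1.0)

    def test_zero_params_zero_regularizer(self):
        params = {"w": parameter(np.zeros(3))}
        pred = _pred([0.6, 0.2], [2.0, 0.0])
        total, bd = joint_loss(pred, np.array([1.0, 0.0]), np.array([3.0, 0.0]),
                               np.array([True, False]), params, gamma=1e-3)
        assert bd.R == 0.0
        assert float(total.data) == pytest.approx(bd.L1 * bd.L2)

    def test_breakdown_identity(self):
        rng = np.random.default_rng(0)
        params = {"w": parameter(rng.standard_normal(4))}
        pred = _pred(rng.random(6), rng.random(6) * 5)
        k = (rng.random(6) > 0.5).astype(float)
        y = rng.integers(1, 6, 6).astype(float)
        total, bd = joint_loss(pred, k, y, k == 1.0, params, gamma=1e-3)
        assert float(total.data) == pytest.approx(bd.L1 * bd.L2 + 1e-3 * bd.R, rel=1e-6)

    def test_no_positive_batch_falls_back_to_additive(self):
        params = {"w": parameter(np.ones(2))}
        pred = _pred([0.3], [2.0])
        total, bd = joint_loss(pred, np.array([0.0]), np.array([0.0]), np.array([False]),
                               params, gamma=0.1)
        assert bd.L2 == 0.0
        assert float(total.data) == pytest.approx(bd.L1 + 0.1 * 2.0)

    def test_multiplicative_coupling_scales_linearly(self):
        # scaling the frequency residuals by sqrt(c) scales total - gamma*R by c
        base_fs, y = np.array([3.0, 2.0]), np.array([5.0, 1.0])
        c = 4.0
        scaled_fs = y + np.sqrt(c) * (base_fs - y)
        k = np.array([1.0, 1.0])
        mask = np.array([True, True])
        t1, _ = joint_loss(_pred([0.5, 0.5], base_fs), k, y, mask, {}, 0.0)
        t2, _ = joint_loss(_pred([0.5, 0.5], scaled_fs), k, y, mask, {}, 0.0)
        assert float(t2.data) == pytest.approx(c * float(t1.data), rel=1e-6)


class TestSchedule:
    def test_lr_before_and_after_decay(self):
        cfg = TrainingConfig(lr=5e-4, lr_decay_epoch=250, lr_decay_factor=0.2)
        assert learning_rate_at(250, cfg) == pytest.approx(5e-4)
        assert learning_rate_at(251, cfg) == pytest.approx(1e-4)

    def test_decay_visible_in_history(self, tiny_features, smoke_config):
        feats, samples, _ = tiny_features
        cfg = replace(smoke_config, max_epochs=4, lr_decay_epoch=2)
        trained = train_model(feats, samples, cfg)
        assert trained.history[1].lr == pytest.approx(cfg.lr)
        assert trained.history[2].lr == pytest.approx(cfg.lr * 0.2)


class TestTraining:
    def test_smoke_run_finishes_with_finite_loss(self, tiny_features, smoke_config):
        feats, samples, _ = tiny_features
        trained = train_model(feats, samples, smoke_config)
        assert len(trained.history) == 2
        assert np.isfinite(trained.history[-1].total)

    def test_batch_log_satisfies_loss_identity(self, tiny_features, smoke_config):
        feats, samples, _ = tiny_features
        trained = train_model(feats, samples, smoke_config)
        assert trained.batch_log
        for b in trained.batch_log:
            assert b.total == pytest.approx(b.L1 * b.L2 + smoke_config.gamma * b.R, rel=1e-4)

    def test_same_seed_identical_final_loss(self, tiny_features, smoke_config):
        feats, samples, _ = tiny_features
        a = train_model(feats, samples, smoke_config)
        b = train_model(feats, samples, smoke_config)
        assert a.history[-1].total == b.history[-1].total

    def test_loss_decreases_monotonically_on_separable_corpus(self):
        # noiseless planted structure, full batch, (almost) no dropout:
        # the optimizer should make steady progress every epoch
        from adrfuse.corpus import build_frequency_matrix, positive_samples, sample_negatives
        from adrfuse.synthetic import SyntheticSpec, generate_corpus
        from adrfuse.text import HashedBagOfWordsEncoder
        from adrfuse.training import prepare_features

        syn = generate_corpus(SyntheticSpec(n_drugs=12, n_side_effects=15, latent_rank=2,
                                            sparsity=0.15, noise_sd=0.0, seed=11))
        matrix = build_frequency_matrix(syn.corpus)
        samples = positive_samples(matrix) + sample_negatives(matrix, 11)
        feats = prepare_features(syn.corpus, syn.drug_chem, syn.drug_disease,
                                 HashedBagOfWordsEncoder(), train_matrix=matrix)
        cfg = TrainingConfig(dim=8, max_epochs=10, batch_size=256, seed=1, dropout=1e-6,
                             gamma=1e-5, fusion_out=8, head_hidden=8, lr=2e-3)
        trained = train_model(feats, samples, cfg)
        totals = [h.total for h in trained.history]
        assert all(b < a for a, b in zip(totals, totals[1:]))

    def test_predictions_bounded(self, tiny_features, smoke_config):
        feats, samples, _ = tiny_features
        trained = train_model(feats, samples, smoke_config)
        asc, fsc = trained.predict([(s.drug_id, s.se_id) for s in samples[:5]])
        assert ((asc > 0) & (asc < 1)).all()
        assert ((fsc >= 1) & (fsc <= 5)).all()

    def test_divergence_raises(self, tiny_features):
        feats, samples, _ = tiny_features
        cfg = TrainingConfig(dim=8, max_epochs=30, batch_size=16, seed=0, lr=1e12,
                             gamma=1e3, fusion_out=8, head_hidden=8)
        with pytest.raises(TrainingDivergence):
            train_model(feats, samples, cfg)

    def test_save_load_round_trip(self, tiny_features, smoke_config, tmp_path):
        feats, samples, _ = tiny_features
        trained = train_model(feats, samples, smoke_config)
        save_params(trained, tmp_path / "m.npz")
        fresh = JointModel(feats, smoke_config, np.random.default_rng(99))
        load_params(fresh, tmp_path / "m.npz")
        pairs = [(s.drug_id, s.se_id) for s in samples[:4]]
        np.testing.assert_allclose(
            fresh.forward_pairs(pairs).AS.data,
            trained.model.forward_pairs(pairs).AS.data,
            atol=1e-6,
        )


class TestGridSearch:
    def test_single_point_grid_returned(self, tiny_features, smoke_config):
        feats, samples, _ = tiny_features
        cfg = replace(smoke_config, max_epochs=1)
        res = inner_grid_search(feats, samples, cfg, dropout_grid=(0.5,), gamma_grid=(1e-4,),
                                n_folds=2)
        assert (res.best_dropout, res.best_gamma) == (0.5, 1e-4)
        assert res.evaluated == [(0.5, 1e-4)]

    def test_full_grid_enumerates_nine_combinations(self, tiny_features, smoke_config):
        feats, samples, _ = tiny_features
        cfg = replace(smoke_config, max_epochs=1)
        res = inner_grid_search(feats, samples, cfg, n_folds=2)
        assert len(res.evaluated) == 9
        assert set(res.evaluated) == {
            (d, g) for d in DEFAULT_DROPOUT_GRID for g in DEFAULT_GAMMA_GRID
        }

    def test_deterministic_for_seed(self, tiny_features, smoke_config):
        feats, samples, _ = tiny_features
        cfg = replace(smoke_config, max_epochs=1)
        r1 = inner_grid_search(feats, samples, cfg, dropout_grid=(0.4, 0.5), gamma_grid=(1e-4,),
                               n_folds=2)
        r2 = inner_grid_search(feats, samples, cfg, dropout_grid=(0.4, 0.5), gamma_grid=(1e-4,),
                               n_folds=2)
        assert r1.scores == r2.scores
        assert (r1.best_dropout, r1.best_gamma) == (r2.best_dropout, r2.best_gamma)

    def test_empty_grid_rejected(self, tiny_features, smoke_config):
        feats, samples, _ = tiny_features
        with pytest.raises(ValueError):
            inner_grid_search(feats, samples, smoke_config, dropout_grid=(), gamma_grid=(1e-4,))


def test_matrix_from_samples_keeps_only_positives():
    samples = [PairSample("D0", "S1", 1, 4), PairSample("D1", "S0", 0)]
    m = matrix_from_samples(samples, ["D0", "D1"], ["S0", "S1"])
    np.testing.assert_array_equal(m.values, [[0, 4], [0, 0]])


class TestValidationSelection:
    def test_best_checkpoint_restored_and_snapshots_kept(self, tiny_features):
        feats, samples, _ = tiny_features
        rng = np.random.default_rng(0)
        order = rng.permutation(len(samples))
        val = [samples[i] for i in order[: len(samples) // 4]]
        fit = [samples[i] for i in order[len(samples) // 4:]]
        from adrfuse.training import train_with_validation
        cfg = TrainingConfig(dim=8, max_epochs=6, batch_size=64, seed=2, dropout=0.4,
                             fusion_out=8, head_hidden=8)
        trained = train_with_validation(feats, fit, val, cfg, eval_every=2, keep_best=2)
        assert 1 <= len(trained.snapshots) <= 2
        assert trained.best_epoch in (2, 4, 6)
        # restored parameters match the best snapshot exactly
        for k, p in trained.model.parameters().items():
            np.testing.assert_array_equal(p.data, trained.snapshots[0][k])

    def test_ensemble_prediction_averages_checkpoints(self, tiny_features):
        feats, samples, _ = tiny_features
        rng = np.random.default_rng(1)
        order = rng.permutation(len(samples))
        val = [samples[i] for i in order[: len(samples) // 4]]
        fit = [samples[i] for i in order[len(samples) // 4:]]
        from adrfuse.training import train_with_validation
        cfg = TrainingConfig(dim=8, max_epochs=6, batch_size=64, seed=2, dropout=0.4,
                             fusion_out=8, head_hidden=8)
        trained = train_with_validation(feats, fit, val, cfg, eval_every=2, keep_best=2)
        pairs = [(s.drug_id, s.se_id) for s in samples[:5]]
        before = {k: p.data.copy() for k, p in trained.model.parameters().items()}
        asc, fsc = trained.predict_ensemble(pairs)
        assert asc.shape == fsc.shape == (5,)
        assert ((fsc >= 1) & (fsc <= 5)).all()
        # ensemble prediction must not disturb the restored parameters
        for k, p in trained.model.parameters().items():
            np.testing.assert_array_equal(p.data, before[k])

    def test_validation_without_positives_rejected(self, tiny_features, smoke_config):
        feats, samples, _ = tiny_features
        negs = [s for s in samples if s.k_hat == 0][:5]
        from adrfuse.training import train_with_validation
        with pytest.raises(ValueError, match="positive"):
            train_with_validation(feats, samples, negs, smoke_config)
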