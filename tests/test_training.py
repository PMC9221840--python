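"""Loss computation, gradient training, meta-learning, LOOCV, grid search."""

import numpy as np
import pytest

from cnode import (
    CNODEModel,
    MetaSettings,
    MicrobiomeDataset,
    TaxonSet,
    TrainingConfig,
    bray_curtis,
    hyperparameter_search,
    leave_one_out,
    meta_episode_update,
    prediction_error,
    predict,
    train,
)
from cnode._grad import loss_and_grad
from cnode.benchmarks import plateau_error

from conftest import random_dataset


class TestPredictionError:
    def test_single_species_samples_are_predicted_exactly(self, rng):
        N = 4
        Z = np.eye(N, dtype=np.int8)
        ds = MicrobiomeDataset.from_matrices(
            TaxonSet.generic(N), Z.astype(float), Z=Z
        )
        model = CNODEModel(rng.normal(size=(N, N)))
        assert prediction_error(model, ds) == 0.0

    def test_zero_theta_is_exact_on_uniform_compositions(self):
        Z = np.array([[1, 1, 0], [1, 1, 1], [0, 1, 1]], dtype=np.int8)
        P = Z / Z.sum(axis=1, keepdims=True)
        ds = MicrobiomeDataset.from_matrices(TaxonSet.generic(3), P, Z=Z)
        assert prediction_error(CNODEModel(np.zeros((3, 3))), ds) == 0.0

    def test_equals_mean_of_per_sample_dissimilarities(self, rng, small_dataset):
        from cnode import predict_batch

        model = CNODEModel(rng.normal(0, 0.2, size=(6, 6)))
        expected = np.mean(
            [
                bray_curtis(s.p, predict(model, s.z))
                for s in small_dataset
            ]
        )
        assert prediction_error(model, small_dataset) == pytest.approx(expected)

    def test_loss_is_sample_weighted_over_concatenation(self, rng):
        """E over D1 + D2 equals the sample-count-weighted mean of the parts."""
        d1 = random_dataset(5, 7, seed=1)
        d2 = random_dataset(5, 3, seed=2)
        model = CNODEModel(rng.normal(0, 0.2, size=(5, 5)))
        e1 = prediction_error(model, d1)
        e2 = prediction_error(model, d2)
        e = prediction_error(model, d1.concat(d2))
        assert e == pytest.approx((7 * e1 + 3 * e2) / 10, abs=1e-12)

    def test_empty_dataset_rejected(self, small_model):
        ds = MicrobiomeDataset(TaxonSet.generic(6), [])
        with pytest.raises(ValueError, match="empty"):
            prediction_error(small_model, ds)


class TestTrain:
    def test_zero_epochs_returns_model_unchanged(self, small_dataset, small_model):
        cfg = TrainingConfig(epochs=0, minibatch_size=4)
        fitted, trace = train(small_model, small_dataset, cfg)
        np.testing.assert_array_equal(fitted.theta, small_model.theta)
        assert trace.epochs == 0

    def test_same_seed_is_bitwise_deterministic(self, small_dataset, small_model):
        cfg = TrainingConfig(epochs=5, minibatch_size=4, seed=3)
        a, _ = train(small_model, small_dataset, cfg)
        b, _ = train(small_model, small_dataset, cfg)
        np.testing.assert_array_equal(a.theta, b.theta)

    def test_oversized_minibatch_rejected(self, small_dataset, small_model):
        cfg = TrainingConfig(epochs=1, minibatch_size=100)
        with pytest.raises(ValueError, match="minibatch"):
            train(small_model, small_dataset, cfg)

    def test_trace_lengths_match_epochs(self, small_dataset, small_model):
        cfg = TrainingConfig(epochs=4, minibatch_size=4)
        _, trace = train(small_model, small_dataset, cfg, test_set=small_dataset)
        assert len(trace.train_errors) == 4
        assert len(trace.test_errors) == 4

    def test_training_halves_the_untrained_test_error(self, capacity_runs):
        """On GLV data (N=10, C=0.5, sigma=0.1, S_train=2N) the trained
        test error beats half the untrained baseline, averaged over 3 seeds."""
        mean_test = np.mean([r.test_error for r in capacity_runs])
        mean_null = np.mean([r.null_error for r in capacity_runs])
        assert mean_test < 0.5 * mean_null

    def test_test_error_reaches_a_plateau(self, capacity_runs):
        """Mean test error over the last 10% of epochs differs from the
        preceding 10% by less than 0.02 (adequate training, low overfitting)."""
        for r in capacity_runs:
            n = max(1, round(len(r.test_trace) * 0.1))
            last = np.mean(r.test_trace[-n:])
            prev = np.mean(r.test_trace[-2 * n : -n])
            assert abs(last - prev) < 0.02

    def test_sgd_optimizer_available(self, small_dataset, small_model):
        cfg = TrainingConfig(
            epochs=2, minibatch_size=4, optimizer="sgd", learning_rate=0.1
        )
        fitted, _ = train(small_model, small_dataset, cfg)
        assert not np.array_equal(fitted.theta, small_model.theta)


class TestMeta:
    def test_zero_inner_steps_is_a_plain_query_step(self, small_dataset):
        model = CNODEModel.initialize(6, seed=1)
        settings = MetaSettings(inner_steps=0, query_fraction=0.5)
        Z, P = small_dataset.Z[:6], small_dataset.P[:6]
        updated = meta_episode_update(
            model, Z, P, settings, learning_rate=0.1, rng=np.random.default_rng(7)
        )
        query = np.random.default_rng(7).permutation(6)[:3]
        _, g = loss_and_grad(model, Z[query], P[query])
        np.testing.assert_array_equal(updated.theta, model.theta - 0.1 * g)

    def test_meta_training_is_deterministic(self, small_dataset):
        model = CNODEModel.initialize(6, seed=2)
        cfg = TrainingConfig(
            epochs=3, minibatch_size=5, meta=MetaSettings(), seed=11
        )
        a, _ = train(model, small_dataset, cfg)
        b, _ = train(model, small_dataset, cfg)
        np.testing.assert_array_equal(a.theta, b.theta)

    def test_meta_mode_is_competitive_with_plain_mode(self):
        """Paired runs on the N=10 GLV task: episodic meta-training reaches
        a mean test error within 1.1x of plain training."""
        from cnode.benchmarks import run_glv_benchmark

        plain_cfg = TrainingConfig(learning_rate=0.02, epochs=80, minibatch_size=5)
        meta_cfg = TrainingConfig(
            learning_rate=0.02, epochs=80, minibatch_size=5, meta=MetaSettings()
        )
        plain, meta = [], []
        for seed in range(3):
            plain.append(run_glv_benchmark(seed, config=plain_cfg).test_error)
            meta.append(run_glv_benchmark(seed, config=meta_cfg).test_error)
        assert np.mean(meta) <= 1.1 * np.mean(plain)

    def test_tiny_episode_rejected(self, small_dataset):
        model = CNODEModel.initialize(6, seed=0)
        with pytest.raises(ValueError, match="at least 2"):
            meta_episode_update(
                model, small_dataset.Z[:1], small_dataset.P[:1],
                MetaSettings(), 0.1,
            )


class TestLeaveOneOut:
    def test_two_sample_structure(self):
        ds = random_dataset(4, 2, seed=5)
        cfg = TrainingConfig(epochs=3, minibatch_size=1)
        result = leave_one_out(ds, cfg)
        assert result.S == 2

    def test_emits_one_bounded_error_per_sample(self):
        ds = random_dataset(5, 6, seed=6)
        cfg = TrainingConfig(epochs=5, minibatch_size=5)
        result = leave_one_out(ds, cfg)
        assert len(result.per_sample_errors) == 6
        assert all(0.0 <= e <= 1.0 for e in result.per_sample_errors)

    def test_constant_map_is_learnable(self):
        """All-identical samples: each fold fits a single point; the median
        fold error is small."""
        one = random_dataset(5, 1, seed=7)
        P = np.tile(one.P, (4, 1))
        Z = np.tile(one.Z, (4, 1))
        ds = MicrobiomeDataset.from_matrices(one.taxa, P, Z=Z)
        cfg = TrainingConfig(epochs=120, minibatch_size=3, learning_rate=0.05)
        result = leave_one_out(ds, cfg)
        assert result.median < 0.05

    def test_single_sample_rejected(self):
        ds = random_dataset(3, 1, seed=8)
        with pytest.raises(ValueError, match="at least 2"):
            leave_one_out(ds, TrainingConfig(epochs=1, minibatch_size=1))


class TestHyperparameterSearch:
    def test_single_config_grid(self):
        ds = random_dataset(4, 6, seed=9)
        cfg = TrainingConfig(epochs=3, minibatch_size=4)
        best, summaries = hyperparameter_search(ds, [cfg], mode="split")
        assert best is cfg and len(summaries) == 1

    def test_duplicated_config_scores_identically(self):
        ds = random_dataset(4, 6, seed=10)
        cfg = TrainingConfig(epochs=3, minibatch_size=4, seed=1)
        _, summaries = hyperparameter_search(ds, [cfg, cfg], mode="split")
        assert summaries[0]["mean_error"] == summaries[1]["mean_error"]

    def test_best_is_argmin_of_reported_summaries(self):
        ds = random_dataset(5, 8, seed=11)
        grid = [
            TrainingConfig(learning_rate=lr, epochs=4, minibatch_size=4)
            for lr in (0.001, 0.02, 0.3)
        ]
        best, summaries = hyperparameter_search(ds, grid, mode="split")
        reported_min = min(s["mean_error"] for s in summaries)
        best_summary = next(s for s in summaries if s["config"] is best)
        assert best_summary["mean_error"] == reported_min

    def test_empty_grid_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="empty"):
            hyperparameter_search(small_dataset, [])


def test_config_validation():
    with pytest.raises(ValueError):
        TrainingConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        TrainingConfig(minibatch_size=0)
    with pytest.raises(ValueError):
        TrainingConfig(dissimilarity="nope")
    with pytest.raises(ValueError):
        MetaSettings(query_fraction=1.0)
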