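"""End-to-end model assembly, residualisation, training and evaluation."""

import numpy as np
import pandas as pd
import pytest

from brainrgin.model_pipeline import (
    BrainRGIN,
    GraphBatch,
    ModelConfig,
    SplitDataset,
    evaluate,
    load_checkpoint,
    residualize_scores,
    save_checkpoint,
    train,
)
from brainrgin.optim import Adam, step_lr
from brainrgin.synthetic_data import SyntheticConfig, generate_cohort, to_split_dataset


def small_cfg(**kw):
    defaults = dict(layer_dims=(8, 8, 8), epochs=3, batch_size=16, patience=0)
    defaults.update(kw)
    return ModelConfig(**defaults)


@pytest.fixture(scope="module")
def tiny_dataset():
    cohort = generate_cohort(SyntheticConfig(n_subjects=48, t_points=80, seed=5))
    return to_split_dataset(cohort)


class TestResidualise:
    def test_scores_linear_in_age_leave_no_residual(self, rng):
        age = rng.uniform(9, 11, size=40)
        scores = 3.0 * age - 5.0
        res = residualize_scores(scores, pd.DataFrame({"age": age}), np.arange(40))
        np.testing.assert_allclose(res, 0.0, atol=1e-8)

    def test_orthogonal_covariate_only_centres(self):
        scores = np.array([1.0, 1.0, -1.0, -1.0]) + 10.0
        cov = pd.DataFrame({"x": [1.0, -1.0, 1.0, -1.0]})  # orthogonal
        res = residualize_scores(scores, cov, np.arange(4))
        np.testing.assert_allclose(res, scores - 10.0, atol=1e-10)

    def test_recovers_noise_variance(self):
        rng = np.random.default_rng(0)
        n = 1000
        age = rng.uniform(9, 11, size=n)
        noise = rng.normal(0, 1.0, size=n)
        res = residualize_scores(2.0 * age + noise,
                                 pd.DataFrame({"age": age}), np.arange(n))
        assert res.var() == pytest.approx(noise.var(), rel=0.05)

    def test_categorical_covariates_are_encoded(self, rng):
        n = 60
        site = rng.integers(0, 3, size=n)
        offs = np.array([0.0, 5.0, -3.0])
        scores = offs[site] + rng.normal(0, 0.1, size=n)
        cov = pd.DataFrame({"site": [f"s{t}" for t in site]})
        res = residualize_scores(scores, cov, np.arange(n))
        assert res.std() < 0.2  # site effect removed

    def test_fit_on_train_only(self, rng):
        n = 50
        age = np.concatenate([rng.uniform(9, 11, 40), rng.uniform(20, 30, 10)])
        scores = age * 2.0
        res = residualize_scores(scores, pd.DataFrame({"age": age}), np.arange(40))
        np.testing.assert_allclose(res[:40], 0.0, atol=1e-8)
        np.testing.assert_allclose(res[40:], 0.0, atol=1e-6)  # same linear law

    def test_rank_deficiency_warns(self, rng):
        age = rng.uniform(9, 11, size=20)
        cov = pd.DataFrame({"a": age, "b": 2 * age})  # collinear
        with pytest.warns(UserWarning, match="rank deficient"):
            residualize_scores(rng.normal(size=20), cov, np.arange(20))


class TestArchitecture:
    def test_node_counts_follow_ceil_rule(self):
        assert ModelConfig().node_counts() == [53, 21, 8, 4]
        assert ModelConfig(pooling_ratio=0.78).node_counts() == [53, 42, 33, 26]

    def test_embedding_width(self):
        assert ModelConfig().embedding_width() == 416
        assert ModelConfig(readout="meanmax").embedding_width() == 832

    def test_forward_is_deterministic(self, tiny_dataset):
        model = BrainRGIN(small_cfg(), seed=0)
        a = model.forward(tiny_dataset.val).pred.data
        b = model.forward(tiny_dataset.val).pred.data
        np.testing.assert_array_equal(a, b)

    def test_forward_reports_block_survivors(self, tiny_dataset):
        model = BrainRGIN(ModelConfig(), seed=0)
        res = model.forward(tiny_dataset.val)
        assert res.ks == [21, 8, 4]
        assert res.selected_roi[0].shape == (len(tiny_dataset.val), 21)

    @pytest.mark.parametrize("readout", ["garo", "meanmax"])
    def test_prediction_invariant_to_node_permutation(self, tiny_dataset, readout):
        rng = np.random.default_rng(7)
        model = BrainRGIN(small_cfg(readout=readout), seed=1)
        batch = tiny_dataset.val.subset(np.arange(3))
        base = model.forward(batch).pred.data
        perm = rng.permutation(batch.features.shape[1])
        permuted = GraphBatch(
            adjacency=batch.adjacency[:, perm][:, :, perm],
            features=batch.features[:, perm],
            roi_index=batch.roi_index[:, perm],
            scores=batch.scores,
        )
        np.testing.assert_allclose(model.forward(permuted).pred.data, base,
                                   atol=1e-5)

    def test_node_count_mismatch_rejected(self, tiny_dataset):
        model = BrainRGIN(small_cfg(n_rois=20), seed=0)
        with pytest.raises(ValueError, match="nodes"):
            model.forward(tiny_dataset.val)

    def test_ratio_one_meanmax_is_pure_conv_stack(self, tiny_dataset):
        model = BrainRGIN(small_cfg(pooling_ratio=1.0, readout="meanmax"), seed=0)
        res = model.forward(tiny_dataset.val.subset(np.arange(2)))
        assert res.ks == [53, 53, 53]
        assert np.all(np.isfinite(res.pred.data))


class TestTraining:
    def test_one_step_updates_every_parameter_group(self, tiny_dataset):
        from brainrgin.losses import LossConfig
        from brainrgin.model_pipeline import _batch_loss

        model = BrainRGIN(small_cfg(), seed=2)
        before = model.state_dict()
        report, _ = _batch_loss(model, tiny_dataset.train.subset(np.arange(8)),
                                LossConfig())
        opt = Adam(model.parameters(), lr=1e-2)
        report.total.backward()
        opt.step()
        groups = {}
        for name, p in model.parameters().items():
            group = name.split(".")[0] + "." + name.split(".")[1]
            groups.setdefault(group, False)
            if not np.array_equal(before[name], p.data):
                groups[group] = True
        missing = [g for g, moved in groups.items() if not moved]
        assert not missing, f"no update reached: {missing}"

    def test_loss_decreases_on_planted_signal(self, tiny_dataset):
        cfg = small_cfg(epochs=5)
        _, hist = train(tiny_dataset, cfg, seed=0)
        assert hist["total"].iloc[-1] < hist["total"].iloc[0]

    def test_lr_schedule_steps_every_30_epochs(self):
        assert step_lr(1e-3, 0, 30, 0.5) == pytest.approx(1e-3)
        assert step_lr(1e-3, 29, 30, 0.5) == pytest.approx(1e-3)
        assert step_lr(1e-3, 30, 30, 0.5) == pytest.approx(5e-4)
        assert step_lr(1e-3, 60, 30, 0.5) == pytest.approx(2.5e-4)

    def test_same_seed_reproduces_weights_bitwise(self, tiny_dataset):
        cfg = small_cfg(epochs=2)
        m1, h1 = train(tiny_dataset, cfg, seed=3)
        m2, h2 = train(tiny_dataset, cfg, seed=3)
        for k, v in m1.state_dict().items():
            np.testing.assert_array_equal(v, m2.state_dict()[k])
        pd.testing.assert_frame_equal(h1, h2)

    def test_empty_training_split_rejected(self, tiny_dataset):
        empty = SplitDataset(
            train=tiny_dataset.train.subset(np.array([], dtype=int)),
            val=tiny_dataset.val,
            test=tiny_dataset.test,
        )
        with pytest.raises(ValueError):
            train(empty, small_cfg(), seed=0)


class _StubModel:
    def __init__(self, fn):
        self._fn = fn

    def predict(self, batch):
        return self._fn(batch)


class TestEvaluate:
    def test_perfect_predictions(self, tiny_dataset):
        metrics = evaluate(_StubModel(lambda b: b.scores.copy()),
                           tiny_dataset.test)
        assert metrics.mse == pytest.approx(0.0)
        assert metrics.pearson_r == pytest.approx(1.0)

    def test_constant_predictions_flagged_degenerate(self, tiny_dataset):
        with pytest.warns(UserWarning, match="constant"):
            metrics = evaluate(_StubModel(lambda b: np.zeros(len(b))),
                               tiny_dataset.test)
        assert metrics.degenerate and metrics.pearson_r == 0.0

    def test_empty_subset_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            evaluate(_StubModel(lambda b: b.scores),
                     tiny_dataset.test.subset(np.array([], dtype=int)))


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tiny_dataset, tmp_path):
        model, _ = train(tiny_dataset, small_cfg(epochs=1), seed=0)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        np.testing.assert_array_equal(
            model.predict(tiny_dataset.test), loaded.predict(tiny_dataset.test)
        )
        assert loaded.cfg == model.cfg
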