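import math

import numpy as np
import pytest

import microdl.training as training_mod
from microdl.config import parse_config_dict
from microdl.data import DatasetSplit, SamplePair
from microdl.models import build_unet
from microdl.training import (TrainingDiverged, compute_loss, loss_grad,
                              train_model)


def loop_mse(p, t):
    total, n = 0.0, 0
    for pv, tv in zip(np.ravel(p), np.ravel(t)):
        total += (pv - tv) ** 2
        n += 1
    return total / n


def loop_bce(p, t, eps=1e-7):
    total, n = 0.0, 0
    for pv, tv in zip(np.ravel(p), np.ravel(t)):
        pv = min(max(pv, eps), 1 - eps)
        total += -(tv * math.log(pv) + (1 - tv) * math.log(1 - pv))
        n += 1
    return total / n


def loop_cce(p, t, eps=1e-7):
    total = 0.0
    for prow, trow in zip(p, t):
        total += -sum(tv * math.log(max(pv, eps)) for pv, tv in zip(prow, trow))
    return total / len(p)


class TestLosses:
    def test_mse_of_identical_arrays_is_zero(self, rng):
        x = rng.random((3, 4))
        assert compute_loss("mse", x, x) == 0.0

    def test_bce_at_half_is_ln_two(self, rng):
        t = (rng.random((4, 4)) > 0.5).astype(float)
        p = np.full((4, 4), 0.5)
        assert abs(compute_loss("binary_crossentropy", p, t) - math.log(2)) < 1e-12

    def test_cce_of_confident_correct_prediction_vanishes(self):
        t = np.array([[1.0, 0.0], [0.0, 1.0]])
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert compute_loss("categorical_crossentropy", p, t) <= 1.2e-7

    @pytest.mark.parametrize("seed", range(5))
    def test_losses_agree_with_scalar_loop_oracles(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random((2, 2))
        t = (rng.random((2, 2)) > 0.5).astype(float)
        assert abs(compute_loss("mse", p, t) - loop_mse(p, t)) < 1e-10
        assert abs(compute_loss("binary_crossentropy", p, t) - loop_bce(p, t)) < 1e-10
        pc = rng.dirichlet(np.ones(3), size=2)
        tc = np.eye(3)[rng.integers(0, 3, size=2)]
        assert abs(compute_loss("categorical_crossentropy", pc, tc)
                   - loop_cce(pc, tc)) < 1e-10

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            compute_loss("mse", rng.random((2, 2)), rng.random((3, 2)))

    @pytest.mark.parametrize("name", ["mse", "binary_crossentropy"])
    def test_loss_grad_matches_finite_difference(self, name, rng):
        p = rng.uniform(0.2, 0.8, size=(3, 3))
        t = (rng.random((3, 3)) > 0.5).astype(float)
        g = loss_grad(name, p, t)
        eps = 1e-5
        for idx in [(0, 0), (1, 2), (2, 1)]:
            pp = p.copy(); pp[idx] += eps
            pm = p.copy(); pm[idx] -= eps
            num = (compute_loss(name, pp, t) - compute_loss(name, pm, t)) / (2 * eps)
            assert abs(num - g[idx]) < 1e-4


def tiny_splits(rng, n=6, size=16):
    pairs = []
    for i in range(n):
        mask = np.zeros((size, size), dtype=np.float32)
        mask[4:10, 4:10] = 1.0
        image = np.clip(mask * 0.6 + 0.2
                        + rng.normal(0, 0.05, (size, size)), 0, 1).astype(np.float32)
        pairs.append(SamplePair(f"s{i}.tif", image, mask))
    return DatasetSplit(train=pairs[:-1], validation=pairs[-1:])


def tiny_config(tmp_path, epochs=2, **kw):
    return parse_config_dict({"use_algorithm": "semantic_segmentation",
                              "path": str(tmp_path),
                              "Iterations_Over_Dataset": epochs,
                              "batchsize": 5, **kw})


class TestTrainingLoop:
    def test_single_epoch_trains_and_checkpoints(self, tmp_path, rng):
        model = build_unet(base_filters=4, rng=rng)
        state = train_model(model, tiny_splits(rng), tiny_config(tmp_path, 1),
                            workdir=tmp_path, log=lambda *a: None)
        assert state.epochs_run == 1
        assert state.best_epoch == 1
        assert state.checkpoint_path.exists()
        assert (tmp_path / "logs" / "training_log.csv").exists()

    def test_early_stopping_rule(self, tmp_path, rng, monkeypatch):
        # scripted validation losses: best at epoch 2, then 3 flat epochs
        scripted = iter([1.0, 0.9, 0.95, 0.96, 0.97, 0.98, 0.99])
        monkeypatch.setattr(training_mod, "evaluate_loss",
                            lambda *a, **k: next(scripted))
        model = build_unet(base_filters=4, rng=rng)
        state = train_model(model, tiny_splits(rng),
                            tiny_config(tmp_path, epochs=10),
                            workdir=tmp_path, patience=3, log=lambda *a: None)
        assert state.epochs_run == 5
        assert state.best_epoch == 2
        assert state.best_val_loss == 0.9

    def test_nan_loss_aborts_with_epoch_and_batch(self, tmp_path, rng, monkeypatch):
        real = training_mod.compute_loss
        calls = {"n": 0}

        def poisoned(name, p, t):
            calls["n"] += 1
            return float("nan") if calls["n"] == 2 else real(name, p, t)

        monkeypatch.setattr(training_mod, "compute_loss", poisoned)
        model = build_unet(base_filters=4, rng=rng)
        with pytest.raises(TrainingDiverged, match="epoch 1"):
            train_model(model, tiny_splits(rng),
                        tiny_config(tmp_path, epochs=2, batchsize=2),
                        workdir=tmp_path, log=lambda *a: None)

    def test_loss_trajectory_reproducible_from_seed(self, tmp_path, rng):
        cfg = tiny_config(tmp_path, epochs=2, seed=11,
                          augmentations=["horizontal_flip"])
        states = []
        for _ in range(2):
            model = build_unet(base_filters=4, rng=np.random.default_rng(3))
            states.append(train_model(model, tiny_splits(np.random.default_rng(8)),
                                      cfg, workdir=tmp_path, log=lambda *a: None))
        assert states[0].batch_order == states[1].batch_order
        assert states[0].train_losses == states[1].train_losses
        assert states[0].val_losses == states[1].val_losses

    def test_small_set_is_learnable(self, tmp_path, rng):
        # overfit smoke test: loss must collapse on a 5-sample problem
        model = build_unet(base_filters=8, rng=np.random.default_rng(0))
        splits = tiny_splits(np.random.default_rng(1))
        state = train_model(model, splits, tiny_config(tmp_path, epochs=100),
                            workdir=tmp_path, patience=100, log=lambda *a: None)
        assert state.train_losses[-1] < 0.1 * state.train_losses[0]

    def test_restored_model_reproduces_best_validation_loss(self, tmp_path, rng):
        model = build_unet(base_filters=4, rng=np.random.default_rng(2))
        splits = tiny_splits(np.random.default_rng(4))
        cfg = tiny_config(tmp_path, epochs=5)
        state = train_model(model, splits, cfg, workdir=tmp_path,
                            log=lambda *a: None)
        re_eval = training_mod.evaluate_loss(model, splits.validation,
                                             cfg.loss, cfg.task, cfg.n_classes)
        assert abs(re_eval - state.best_val_loss) < 1e-5
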