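"""Masked-loss training: loss restriction, splits, convergence, checkpointing."""

import numpy as np
import pytest

from cycloct.msd_network import MSDConfig, forward, init_parameters
from cycloct.sampling import PartialSinogram
from cycloct.training import (
    TrainConfig, TrainingSet, apply_model, masked_loss, split_train_val, train,
)


def make_partial(values, defined_rows):
    defined = np.zeros(values.shape, dtype=bool)
    defined[defined_rows, :] = True
    vals = np.where(defined, values, np.nan)
    return PartialSinogram(values=vals, defined=defined)


class TestMaskedLoss:
    def test_zero_on_domain_match_and_single_pixel(self):
        rng = np.random.default_rng(0)
        target_vals = rng.random((8, 8))
        target = make_partial(target_vals, [1, 4])
        pred = np.where(target.defined, target.values, rng.random((8, 8)))
        assert masked_loss(pred, target) == 0.0

        one = PartialSinogram(values=np.where(np.eye(4, dtype=bool)[:1].T @ np.ones((1, 4), bool), 0.0, np.nan),
                              defined=np.zeros((4, 4), bool))
        one.defined[2, 3] = True
        one.values = np.where(one.defined, 1.0, np.nan)
        pred = np.zeros((4, 4))
        pred[2, 3] = 1.0 + 0.25
        assert masked_loss(pred, one) == pytest.approx(0.25 ** 2)

    def test_full_domain_equals_naive_double_loop(self):
        rng = np.random.default_rng(1)
        t = rng.random((6, 7))
        target = make_partial(t, list(range(6)))
        pred = rng.random((6, 7))
        naive = 0.0
        for i in range(6):
            for j in range(7):
                naive += (pred[i, j] - t[i, j]) ** 2
        assert masked_loss(pred, target) == pytest.approx(naive, rel=1e-12)

    def test_invariant_to_perturbations_outside_domain(self):
        rng = np.random.default_rng(2)
        t = rng.random((10, 10))
        target = make_partial(t, [0, 3, 7])
        pred = rng.random((10, 10))
        base = masked_loss(pred, target)
        for _ in range(25):
            fuzz = pred.copy()
            outside = ~target.defined
            idx = rng.choice(np.flatnonzero(outside), 5, replace=False)
            fuzz.ravel()[idx] += rng.standard_normal(5) * 100
            assert masked_loss(fuzz, target) == base

    def test_empty_domain_raises(self):
        target = make_partial(np.zeros((4, 4)), [])
        with pytest.raises(ValueError, match="empty"):
            masked_loss(np.zeros((4, 4)), target)


class TestSplit:
    def test_paper_scale_sizes(self):
        tr, va = split_train_val(1024, 0.9, seed=0)
        assert (len(tr), len(va)) == (922, 102)
        assert sorted(tr + va) == list(range(1024))

    def test_small_n_and_determinism(self):
        tr, va = split_train_val(10, 0.9, seed=3)
        assert (len(tr), len(va)) == (9, 1)
        assert split_train_val(10, 0.9, seed=3) == (tr, va)
        assert split_train_val(10, 0.9, seed=4) != (tr, va)


def identity_task(n=5, size=48, seed=0):
    """Sinograms whose target equals the input on all rows."""
    rng = np.random.default_rng(seed)
    base = rng.random((size, size))
    inputs, targets = [], []
    for _ in range(n):
        x = base + 0.05 * rng.standard_normal((size, size))
        inputs.append(x)
        targets.append(make_partial(x, list(range(size))))
    return TrainingSet(inputs, targets)


class TestTrain:
    def test_identity_task_converges(self):
        cfg = MSDConfig(depth=10, dilation_cycle=(1, 2, 3), seed=0)
        trainset = identity_task(n=5, size=32)
        tcfg = TrainConfig(max_epochs=150, learning_rate=0.01,
                           train_fraction=0.8, seed=0)
        model, log = train(cfg, None, trainset, tcfg)
        assert model.meta["best_val_loss"] < 0.01 * log.val_loss[0]

    def test_zero_epoch_budget_returns_initial_parameters(self):
        cfg = MSDConfig(depth=3, seed=1)
        p0 = init_parameters(cfg)
        model, log = train(cfg, p0, identity_task(n=3),
                           TrainConfig(max_epochs=0, train_fraction=0.7, seed=0))
        assert np.array_equal(model.params.pack(), p0.pack())
        assert log.epochs == []

    def test_checkpoint_is_validation_argmin(self):
        cfg = MSDConfig(depth=4, dilation_cycle=(1, 2), seed=2)
        model, log = train(cfg, None, identity_task(n=4, size=32),
                           TrainConfig(max_epochs=8, train_fraction=0.75, seed=1))
        best = model.meta["best_val_loss"]
        assert all(best <= v + 1e-15 for v in log.val_loss)

    def test_full_domain_masked_equals_unmasked_descent(self):
        """With D = all pixels the masked objective IS the plain sum of
        squares; identical seeds must give identical trajectories."""
        cfg = MSDConfig(depth=3, dilation_cycle=(1, 2), seed=3)
        ts = identity_task(n=3, size=24)
        m1, l1 = train(cfg, None, ts, TrainConfig(max_epochs=3, seed=5))
        m2, l2 = train(cfg, None, ts, TrainConfig(max_epochs=3, seed=5))
        assert np.array_equal(m1.params.pack(), m2.params.pack())
        assert l1.val_loss == l2.val_loss

    def test_divergence_aborts_with_diagnostic(self):
        cfg = MSDConfig(depth=2, seed=0)
        ts = identity_task(n=3, size=16)
        bad = TrainConfig(max_epochs=5, learning_rate=1e160, seed=0)
        with pytest.raises((FloatingPointError, ValueError)):
            with np.errstate(over="ignore", invalid="ignore"):
                train(cfg, None, ts, bad)


class TestApply:
    def test_identity_configured_model_returns_inputs(self):
        from cycloct.msd_network import MSDModel
        cfg = MSDConfig(depth=2, seed=0)
        p = init_parameters(cfg)
        p.final_weights[0] = 1.0
        model = MSDModel(cfg, p)  # unit normalization
        xs = [np.random.default_rng(7).random((12, 12))]
        out = apply_model(model, xs)
        assert np.allclose(out[0], xs[0])

    def test_restoration_approaches_noiseless_truth_on_supervised_rows(self, tiny_results):
        """The network is trained against *noisy* dithered rows, yet on those
        rows its output lands much closer to the noiseless truth than the
        bicubic input does — it restores and denoises rather than memorizing
        the noise.  (Evaluated on every slice of the desk-scale scan.)"""
        from cycloct.sampling import select_training_angles
        _, artifacts = tiny_results
        cyc = artifacts["cycloidal"]
        scan = artifacts["scan"]
        n_angles = scan.noiseless[0].values.shape[0]
        rows = select_training_angles(n_angles, 13)
        err_net, err_bicubic = 0.0, 0.0
        for i, clean in enumerate(scan.noiseless):
            truth = clean.values[rows]
            err_net += float(np.mean((cyc.restored[i][rows] - truth) ** 2))
            err_bicubic += float(np.mean((cyc.interpolated[i][rows] - truth) ** 2))
        assert err_net < err_bicubic

    def test_output_shape_preserved_and_refeedable(self):
        cfg = MSDConfig(depth=3, seed=4)
        model, _ = train(cfg, None, identity_task(n=3, size=20),
                         TrainConfig(max_epochs=1, seed=0))
        out = apply_model(model, [np.random.default_rng(0).random((20, 20))])
        assert out[0].shape == (20, 20)
        out2 = apply_model(model, out)
        assert out2[0].shape == (20, 20)
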