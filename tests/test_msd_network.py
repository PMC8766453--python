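"""MS-D network: forward/backward correctness, init statistics, checkpoints."""

import numpy as np
import pytest

from cycloct.msd_network import (
    MSDConfig, MSDModel, MSDParameters, backward, count_parameters, forward,
    init_parameters, load_model, save_model,
)


def random_params(config, seed=1, scale=0.4):
    rng = np.random.default_rng(seed)
    p = init_parameters(config)
    for k in p.kernels:
        k[...] = rng.normal(0, scale, k.shape)
    p.biases[...] = rng.normal(0, 0.1, p.biases.shape)
    p.final_weights[...] = rng.normal(0, scale, p.final_weights.shape)
    p.final_bias = float(rng.normal())
    return p


def brute_force_forward(x, p, cfg):
    """Nested-loop evaluation of the layer formulas (independent oracle)."""
    H, W = x.shape
    z = [x]
    for i in range(1, cfg.depth + 1):
        d = cfg.dilation(i)
        a = np.full((H, W), p.biases[i - 1])
        for c in range(i):
            for y in range(H):
                for xx in range(W):
                    acc = 0.0
                    for u in (-1, 0, 1):
                        for v in (-1, 0, 1):
                            yy, xc = y + u * d, xx + v * d
                            if 0 <= yy < H and 0 <= xc < W:
                                acc += p.kernels[i - 1][c, u + 1, v + 1] * z[c][yy, xc]
                    a[y, xx] += acc
        z.append(np.maximum(a, 0.0))
    out = np.full((H, W), p.final_bias)
    for c in range(cfg.depth + 1):
        out += p.final_weights[c] * z[c]
    return out


class TestForward:
    def test_all_zero_weights_give_constant_bias(self):
        cfg = MSDConfig(depth=3, dilation_cycle=(1, 2), seed=0)
        p = init_parameters(cfg)
        p.final_bias = 2.5
        out = forward(np.random.default_rng(0).random((12, 9)), p, cfg)
        assert np.allclose(out, 2.5)

    def test_identity_final_map(self):
        cfg = MSDConfig(depth=3, dilation_cycle=(1,), seed=0)
        p = init_parameters(cfg)
        for k in p.kernels:
            k[...] = 0.0
        p.final_weights[0] = 1.0
        x = np.random.default_rng(1).random((7, 11))
        assert np.allclose(forward(x, p, cfg), x)

    def test_matches_brute_force_oracle(self):
        cfg = MSDConfig(depth=2, dilation_cycle=(1, 2), seed=0)
        p = random_params(cfg, seed=2)
        x = np.random.default_rng(3).standard_normal((8, 8))
        fast = forward(x, p, cfg)
        slow = brute_force_forward(x, p, cfg)
        assert np.abs(fast - slow).max() <= 1e-5 * np.abs(slow).max()

    def test_fully_convolutional_translation_equivariance(self):
        """Constant inputs of different sizes give the same interior value."""
        cfg = MSDConfig(depth=4, dilation_cycle=(1, 2), seed=0)
        p = random_params(cfg, seed=4, scale=0.2)
        a = forward(np.ones((24, 24)), p, cfg)
        b = forward(np.ones((48, 48)), p, cfg)
        # away from borders (max receptive field reach of 4 layers, dil <= 2)
        m = 10
        assert a[12, 12] == pytest.approx(b[24, 24], rel=1e-12)
        assert np.allclose(a[m:-m, m:-m], a[12, 12])
        assert np.allclose(b[m:-m, m:-m], a[12, 12])

    def test_rejects_bad_input(self):
        cfg = MSDConfig(depth=1, seed=0)
        p = init_parameters(cfg)
        with pytest.raises(ValueError):
            forward(np.array([[np.nan, 1.0]]), p, cfg)
        with pytest.raises(ValueError):
            forward(np.ones(5), p, cfg)


class TestBackward:
    def test_gradients_match_finite_differences(self):
        cfg = MSDConfig(depth=4, dilation_cycle=(1, 2), seed=0)
        p = random_params(cfg, seed=5, scale=0.3)
        rng = np.random.default_rng(6)
        x = rng.standard_normal((16, 16))
        t = rng.standard_normal((16, 16))
        y, state = forward(x, p, cfg, return_state=True)
        g = backward(2.0 * (y - t), state, p, cfg).pack()
        flat = p.pack()
        for i in rng.choice(flat.size, 20, replace=False):
            eps = 1e-6
            f = flat.copy()
            f[i] += eps
            q = p.copy(); q.unpack_into(f)
            lp = float(np.sum((forward(x, q, cfg) - t) ** 2))
            f[i] -= 2 * eps
            q.unpack_into(f)
            lm = float(np.sum((forward(x, q, cfg) - t) ** 2))
            fd = (lp - lm) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestInit:
    def test_variance_scales_inversely_with_fan_in(self):
        """Layer 1 (fan-in 9) weight variance exceeds layer 50 (fan-in 450)
        by a factor of ~50; estimated over >= 10^4 draws via repeated init."""
        cfg = MSDConfig(depth=50, dilation_cycle=(1,), seed=0)
        w1, w50 = [], []
        for s in range(30):
            p = init_parameters(MSDConfig(depth=50, dilation_cycle=(1,), seed=s))
            w1.append(p.kernels[0].ravel())
            w50.append(p.kernels[49].ravel())
        v1 = np.concatenate(w1).var()
        v50 = np.concatenate(w50).var()
        assert len(np.concatenate(w50)) >= 10_000
        assert v1 / v50 == pytest.approx(50.0, rel=0.1)

    def test_same_seed_identical_and_zero_output(self):
        cfg = MSDConfig(depth=6, seed=11)
        a, b = init_parameters(cfg), init_parameters(cfg)
        assert np.array_equal(a.pack(), b.pack())
        out = forward(np.random.default_rng(0).random((9, 9)), a, cfg)
        assert np.allclose(out, 0.0)


class TestParameterCount:
    @pytest.mark.parametrize("depth,expected", [(1, 13), (100, 45652)])
    def test_closed_form(self, depth, expected):
        assert count_parameters(MSDConfig(depth=depth)) == expected

    def test_matches_instantiated_scalars(self):
        cfg = MSDConfig(depth=7, dilation_cycle=(1, 2, 3), seed=0)
        assert init_parameters(cfg).n_scalars() == count_parameters(cfg)


def test_checkpoint_round_trip_bit_exact(tmp_path):
    cfg = MSDConfig(depth=4, dilation_cycle=(1, 3), seed=9)
    model = MSDModel(cfg, random_params(cfg, seed=9), in_mean=0.3, in_std=1.7,
                     out_mean=-0.1, out_std=2.2, meta={"best_val_loss": 0.123})
    p = str(tmp_path / "model.h5")
    save_model(p, model)
    m2 = load_model(p)
    assert m2.config == cfg
    assert np.array_equal(m2.params.pack(), model.params.pack())
    assert (m2.in_mean, m2.in_std, m2.out_mean, m2.out_std) == (0.3, 1.7, -0.1, 2.2)
    assert m2.meta["best_val_loss"] == 0.123
    x = np.random.default_rng(1).random((6, 6))
    assert np.array_equal(m2.predict(x), model.predict(x))
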