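"""Mixed-Scale Dense (MS-D) convolutional network, implemented from scratch.

The MS-D architecture differs from encoder-decoder CNNs in two ways: it
captures multi-scale structure exclusively through *dilated* 3x3
convolutions (no down/up-sampling), and it is *densely* connected — every
layer takes the input image plus all previous layer outputs as channels.
With one channel per layer this yields a network with very few parameters
(45,652 at depth 100) that trains well on small data and processes
arbitrarily large images fully convolutionally.

Layer i (1-based) computes, with dilation ``d_i`` cycling through the
dilation list,

    z_i = ReLU( b_i + sum_{c in {x, z_1 .. z_{i-1}}} conv3x3_{d_i}(z_c) )

and the output is an affine map over all images,

    y = b_out + sum_{c in {x, z_1 .. z_L}} v_c * z_c .

Convolutions use zero padding so every intermediate image keeps the input
shape.  Forward and backward passes are written directly in numpy
(shift-and-accumulate over the nine kernel taps), with gradients validated
against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

_OFFSETS = [(u, v) for u in (-1, 0, 1) for v in (-1, 0, 1)]


@dataclass(frozen=True)
class MSDConfig:
    """Architecture hyperparameters.

    depth
        Number of hidden layers L (one channel each).
    dilation_cycle
        Dilations assigned round-robin: layer i uses
        ``dilation_cycle[(i - 1) % len]``.  Default 1..10.
    seed
        Seed for parameter initialization.
    """

    depth: int = 100
    dilation_cycle: tuple[int, ...] = tuple(range(1, 11))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not self.dilation_cycle or any(d < 1 for d in self.dilation_cycle):
            raise ValueError("dilations must be >= 1")
        object.__setattr__(self, "dilation_cycle", tuple(int(d) for d in self.dilation_cycle))

    def dilation(self, layer: int) -> int:
        """Dilation of 1-based layer index."""
        return self.dilation_cycle[(layer - 1) % len(self.dilation_cycle)]


@dataclass
class MSDParameters:
    """Learnable parameters: per-layer dilated kernels and the final 1x1 map.

    ``kernels[i]`` has shape (i+1, 3, 3): one 3x3 kernel per input channel of
    hidden layer i+1 (the input image plus the i previous layer outputs).
    ``final_weights`` has one scalar per image (input + all L layers).
    """

    kernels: list[np.ndarray]
    biases: np.ndarray  # (L,)
    final_weights: np.ndarray  # (L + 1,)
    final_bias: float

    def copy(self) -> "MSDParameters":
        return MSDParameters(
            [k.copy() for k in self.kernels],
            self.biases.copy(),
            self.final_weights.copy(),
            float(self.final_bias),
        )

    def n_scalars(self) -> int:
        return (
            sum(k.size for k in self.kernels)
            + self.biases.size
            + self.final_weights.size
            + 1
        )

    # flat-vector packing used by the optimizer
    def pack(self) -> np.ndarray:
        parts = [k.ravel() for k in self.kernels]
        parts += [self.biases, self.final_weights, np.array([self.final_bias])]
        return np.concatenate(parts)

    def unpack_into(self, flat: np.ndarray) -> None:
        pos = 0
        for k in self.kernels:
            k[...] = flat[pos:pos + k.size].reshape(k.shape)
            pos += k.size
        self.biases[...] = flat[pos:pos + self.biases.size]
        pos += self.biases.size
        self.final_weights[...] = flat[pos:pos + self.final_weights.size]
        pos += self.final_weights.size
        self.final_bias = float(flat[pos])


def count_parameters(config: MSDConfig) -> int:
    """Closed-form number of scalars: sum_i(9i + 1) + (L + 1) + 1."""
    L = config.depth
    return 9 * L * (L + 1) // 2 + L + (L + 1) + 1


def init_parameters(config: MSDConfig) -> MSDParameters:
    """He-style initialization adapted to the dense connectivity.

    Convolution weights are zero-mean normal with variance 2 / fan_in where
    fan_in = 9 x (number of input channels of that layer); biases and all
    final-map weights start at zero, so the initial network output is
    identically zero.
    """
    rng = np.random.default_rng(config.seed)
    kernels = []
    for i in range(1, config.depth + 1):
        fan_in = 9 * i
        kernels.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(i, 3, 3)))
    return MSDParameters(
        kernels=kernels,
        biases=np.zeros(config.depth),
        final_weights=np.zeros(config.depth + 1),
        final_bias=0.0,
    )


def _conv_accumulate(out: np.ndarray, stack: np.ndarray, taps: np.ndarray, d: int) -> None:
    """out += sum_c correlate(stack[c], taps[c]) with dilation d, zero padding.

    ``out[y, x] += sum_{c,u,v} taps[c, u+1, v+1] * stack[c, y + u*d, x + v*d]``.
    """
    H, W = out.shape
    for u, v in _OFFSETS:
        dy, dx = u * d, v * d
        ys0, ys1 = max(dy, 0), H + min(dy, 0)
        xs0, xs1 = max(dx, 0), W + min(dx, 0)
        if ys0 >= ys1 or xs0 >= xs1:
            continue
        yt0, yt1 = max(-dy, 0), H + min(-dy, 0)
        xt0, xt1 = max(-dx, 0), W + min(-dx, 0)
        w = taps[:, u + 1, v + 1]
        out[yt0:yt1, xt0:xt1] += np.tensordot(w, stack[:, ys0:ys1, xs0:xs1], axes=(0, 0))


def forward(
    x: np.ndarray, params: MSDParameters, config: MSDConfig,
    return_state: bool = False,
):
    """Evaluate the network on a single-channel image of any shape.

    Returns the output image; with ``return_state=True`` also returns the
    (L+1, H, W) stack of all images for use by :func:`backward`.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("input must be a 2-D image")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    L = config.depth
    H, W = x.shape
    z = np.empty((L + 1, H, W))
    z[0] = x
    for i in range(1, L + 1):
        a = np.full((H, W), params.biases[i - 1])
        _conv_accumulate(a, z[:i], params.kernels[i - 1], config.dilation(i))
        z[i] = np.maximum(a, 0.0)
    y = params.final_bias + np.tensordot(params.final_weights, z, axes=(0, 0))
    if return_state:
        return y, z
    return y


def backward(
    grad_out: np.ndarray, z: np.ndarray, params: MSDParameters, config: MSDConfig,
) -> MSDParameters:
    """Gradient of a scalar loss w.r.t. all parameters.

    ``grad_out`` is dLoss/dOutput (same shape as the image); ``z`` is the
    image stack returned by :func:`forward`.  Returns gradients in an
    MSDParameters of matching shapes.
    """
    L = config.depth
    g_kernels = [np.zeros_like(k) for k in params.kernels]
    g_biases = np.zeros(L)
    g_final = np.tensordot(z, grad_out, axes=((1, 2), (0, 1)))
    g_final_bias = float(grad_out.sum())

    dz = params.final_weights[:, None, None] * grad_out[None, :, :]
    H, W = grad_out.shape
    for i in range(L, 0, -1):
        da = np.where(z[i] > 0.0, dz[i], 0.0)  # ReLU gate
        g_biases[i - 1] = da.sum()
        d = config.dilation(i)
        gk = g_kernels[i - 1]
        for u, v in _OFFSETS:
            dy, dx = u * d, v * d
            ys0, ys1 = max(dy, 0), H + min(dy, 0)
            xs0, xs1 = max(dx, 0), W + min(dx, 0)
            if ys0 >= ys1 or xs0 >= xs1:
                continue
            yt0, yt1 = max(-dy, 0), H + min(-dy, 0)
            xt0, xt1 = max(-dx, 0), W + min(-dx, 0)
            da_part = da[yt0:yt1, xt0:xt1]
            # weight gradients: correlation of input images with da
            gk[:, u + 1, v + 1] += np.tensordot(
                z[:i, ys0:ys1, xs0:xs1], da_part, axes=((1, 2), (0, 1))
            )
            # input gradients: transpose convolution (opposite shift)
            w = params.kernels[i - 1][:, u + 1, v + 1]
            dz[:i, ys0:ys1, xs0:xs1] += w[:, None, None] * da_part[None, :, :]
    return MSDParameters(g_kernels, g_biases, g_final, g_final_bias)


# ---------------------------------------------------------------------------
# trained-model container and checkpointing

@dataclass
class MSDModel:
    """A network together with its input/output normalization constants.

    Inputs are standardized with training-set statistics before the forward
    pass and outputs are produced in normalized target space, then
    de-normalized: ``y = out_mean + out_std * net((x - in_mean) / in_std)``.
    """

    config: MSDConfig
    params: MSDParameters
    in_mean: float = 0.0
    in_std: float = 1.0
    out_mean: float = 0.0
    out_std: float = 1.0
    meta: dict = field(default_factory=dict)

    def predict(self, x: np.ndarray) -> np.ndarray:
        net = forward((np.asarray(x, float) - self.in_mean) / self.in_std,
                      self.params, self.config)
        return self.out_mean + self.out_std * net


def save_model(path: str, model: MSDModel) -> None:
    """Write a bit-exact checkpoint (HDF5)."""
    with h5py.File(path, "w") as f:
        f.attrs["depth"] = model.config.depth
        f.attrs["dilation_cycle"] = list(model.config.dilation_cycle)
        f.attrs["seed"] = model.config.seed
        for k in ("in_mean", "in_std", "out_mean", "out_std"):
            f.attrs[k] = getattr(model, k)
        for key, val in model.meta.items():
            f.attrs[f"meta_{key}"] = val
        g = f.create_group("layers")
        for i, k in enumerate(model.params.kernels):
            g.create_dataset(f"kernel_{i:04d}", data=k, track_times=False)
        f.create_dataset("biases", data=model.params.biases, track_times=False)
        f.create_dataset("final_weights", data=model.params.final_weights, track_times=False)
        f.attrs["final_bias"] = model.params.final_bias


def load_model(path: str) -> MSDModel:
    with h5py.File(path, "r") as f:
        config = MSDConfig(
            depth=int(f.attrs["depth"]),
            dilation_cycle=tuple(int(d) for d in f.attrs["dilation_cycle"]),
            seed=int(f.attrs["seed"]),
        )
        kernels = [f["layers"][f"kernel_{i:04d}"][()] for i in range(config.depth)]
        params = MSDParameters(
            kernels, f["biases"][()], f["final_weights"][()],
            float(f.attrs["final_bias"]),
        )
        meta = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")}
        return MSDModel(
            config, params,
            in_mean=float(f.attrs["in_mean"]), in_std=float(f.attrs["in_std"]),
            out_mean=float(f.attrs["out_mean"]), out_std=float(f.attrs["out_std"]),
            meta=meta,
        )
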