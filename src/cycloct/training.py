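"""In-scan supervised training with a loss restricted to measured pixels.

The training pairs are produced by the scan itself: inputs are the bicubic
interpolated cycloidal sinograms ("low-dose full sinograms") and targets
are the partial sinograms holding the fully dithered training projections
("full-dose partial sinograms").  The loss for one pair is the sum of
squared errors over exactly the pixels where the partial sinogram holds a
measurement,

    L_cyc(f(x), y) = sum_{j in D} (f(x)^j - y^j)^2 ,

so the network is supervised only where ground-truth data exist, and
undefined pixels contribute nothing.  Training minimizes this loss with
ADAM, one full sinogram per step; the parameters with the lowest mean
masked validation loss are kept.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .msd_network import (
    MSDConfig, MSDModel, MSDParameters, backward, forward, init_parameters,
)
from .sampling import PartialSinogram


@dataclass
class TrainingSet:
    """Paired inputs (complete interpolated sinograms) and partial targets."""

    inputs: list[np.ndarray]
    targets: list[PartialSinogram]

    def __post_init__(self) -> None:
        if len(self.inputs) != len(self.targets):
            raise ValueError("inputs/targets length mismatch")
        for x, y in zip(self.inputs, self.targets):
            if x.shape != y.values.shape:
                raise ValueError("input/target shape mismatch")

    def __len__(self) -> int:
        return len(self.inputs)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    train_fraction: float = 0.9
    max_epochs: int = 100
    max_seconds: float | None = None
    seed: int = 0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class TrainLog:
    """Per-epoch training curve; losses are mean masked loss per defined pixel."""

    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    wall_time: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_csv(self, path: str) -> None:
        with open(path, "w") as f:
            f.write("epoch,train_loss,val_loss,wall_time\n")
            for e, t, v, w in zip(self.epochs, self.train_loss, self.val_loss,
                                  self.wall_time):
                f.write(f"{e},{t!r},{v!r},{w!r}\n")


def masked_loss(pred: np.ndarray, target: PartialSinogram) -> float:
    """Sum of squared differences over the defined pixels of the target."""
    if pred.shape != target.values.shape:
        raise ValueError("shape mismatch")
    D = target.defined
    if not D.any():
        raise ValueError("target has an empty measurement domain: no supervision")
    diff = pred[D] - target.values[D]
    return float(np.dot(diff, diff))


def split_train_val(n: int, train_fraction: float, seed: int) -> tuple[list[int], list[int]]:
    """Disjoint, exhaustive random split with |train| = round(fraction * n)."""
    if n < 2:
        raise ValueError("need at least 2 sinograms to split")
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return sorted(perm[:n_train].tolist()), sorted(perm[n_train:].tolist())


def _adam_state(shape_like: np.ndarray):
    return np.zeros_like(shape_like), np.zeros_like(shape_like)


def train(
    net_config: MSDConfig,
    params0: MSDParameters | None,
    trainset: TrainingSet,
    cfg: TrainConfig,
) -> tuple[MSDModel, TrainLog]:
    """Minimize the masked loss by ADAM; return the validation-best model.

    One ADAM step per training sinogram (images processed whole, no
    patching); after every epoch the mean per-pixel masked loss on the
    validation subset is evaluated and the best parameters are retained.
    The reported losses are normalized by |D| for comparability; the
    optimized quantity is the raw sum.
    """
    if len(trainset) == 0:
        raise ValueError("empty training set")
    for y in trainset.targets:
        if not y.defined.any():
            raise ValueError("a target has an empty measurement domain")

    params = (params0 or init_parameters(net_config)).copy()

    # normalization constants from the training data
    in_all = np.concatenate([x.ravel() for x in trainset.inputs])
    out_all = np.concatenate(
        [y.values[y.defined].ravel() for y in trainset.targets]
    )
    in_mean, in_std = float(in_all.mean()), float(in_all.std()) or 1.0
    out_mean, out_std = float(out_all.mean()), float(out_all.std()) or 1.0

    xs = [(np.asarray(x, float) - in_mean) / in_std for x in trainset.inputs]
    ys = [(y.values - out_mean) / out_std for y in trainset.targets]
    Ds = [y.defined for y in trainset.targets]

    train_idx, val_idx = split_train_val(len(trainset), cfg.train_fraction, cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)

    flat = params.pack()
    m, v = _adam_state(flat)
    t_step = 0
    lr, b1, b2, eps = cfg.learning_rate, cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps

    def val_mean_loss() -> float:
        tot, npix = 0.0, 0
        for i in val_idx:
            pred = forward(xs[i], params, net_config)
            D = Ds[i]
            diff = pred[D] - ys[i][D]
            tot += float(np.dot(diff, diff))
            npix += int(D.sum())
        return tot / max(npix, 1)

    log = TrainLog()
    best = params.copy()
    best_val = val_mean_loss()
    best_epoch = 0
    t0 = time.monotonic()

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(train_idx))
        ep_tot, ep_pix = 0.0, 0
        for k in order:
            i = train_idx[k]
            pred, state = forward(xs[i], params, net_config, return_state=True)
            D = Ds[i]
            resid = np.where(D, pred - ys[i], 0.0)
            loss = float(np.sum(resid * resid))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            ep_tot += loss
            ep_pix += int(D.sum())
            grads = backward(2.0 * resid, state, params, net_config)
            g = grads.pack()
            t_step += 1
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            mh = m / (1 - b1 ** t_step)
            vh = v / (1 - b2 ** t_step)
            flat = params.pack() - lr * mh / (np.sqrt(vh) + eps)
            params.unpack_into(flat)

        vl = val_mean_loss()
        log.epochs.append(epoch)
        # logged in raw target units (normalized loss scaled by out_std^2)
        log.train_loss.append(ep_tot / max(ep_pix, 1) * out_std ** 2)
        log.val_loss.append(vl * out_std ** 2)
        log.wall_time.append(time.monotonic() - t0)
        if vl < best_val:
            best_val, best_epoch = vl, epoch
            best = params.copy()
        if cfg.max_seconds is not None and time.monotonic() - t0 > cfg.max_seconds:
            break

    log.best_epoch = best_epoch
    model = MSDModel(
        net_config, best,
        in_mean=in_mean, in_std=in_std, out_mean=out_mean, out_std=out_std,
        meta={"best_val_loss": best_val * out_std ** 2, "best_epoch": best_epoch,
              "n_train": len(train_idx), "n_val": len(val_idx)},
    )
    return model, log


def apply_model(model: MSDModel, sinogram_values: list[np.ndarray]) -> list[np.ndarray]:
    """Run the trained network on interpolated sinograms (restored sinograms)."""
    return [model.predict(x) for x in sinogram_values]
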