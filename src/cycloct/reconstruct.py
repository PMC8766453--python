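"""Tomographic reconstruction: filtered back projection and TV minimization.

FBP ramp-filters each projection (pure Ram-Lak, applied in the Fourier
domain on zero-padded rows) and back-projects with linear interpolation,
scaled so the result approximates the attenuation map in physical units
(discretizing f = int_0^pi q_theta(s) dtheta as (pi / n_angles) * sum).

TV reconstruction approximately minimizes

    (1/2) ||A u - b||^2 + lambda * TV(u)

with isotropic total variation (forward differences, Neumann boundary) by
the Chambolle-Pock primal-dual algorithm.  The discrete forward operator A
is a sparse matrix built by ray marching with bilinear interpolation, so
its adjoint is exact.

Image convention matches the phantom rasterizer: pixel centers at
-1 + (j + 0.5) * pixel_size in x (columns) and in y (rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .forward_model import Geometry, Sinogram


@dataclass
class ReconImage:
    values: np.ndarray  # (grid_n, grid_n)
    pixel_size: float
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TVConfig:
    tv_weight: float = 1e-3
    n_iterations: int = 300
    step_ratio: float = 1.0  # sigma / tau

    def __post_init__(self) -> None:
        if self.tv_weight < 0:
            raise ValueError("tv_weight must be >= 0")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def _image_grid(grid_n: int) -> tuple[np.ndarray, np.ndarray, float]:
    px = 2.0 / grid_n
    c = -1.0 + (np.arange(grid_n) + 0.5) * px
    x, y = np.meshgrid(c, c, indexing="xy")  # row index -> y, col index -> x
    return x, y, px


def fbp(sino: Sinogram, grid_n: int) -> ReconImage:
    """Ram-Lak filtered back projection onto a grid_n x grid_n image."""
    vals = sino.values
    if not np.all(np.isfinite(vals)):
        raise ValueError("sinogram contains missing entries; complete it first")
    g = sino.geometry
    n_cols = g.n_cols
    ds = g.pixel_size

    # Ram-Lak filter from its exact spatial-domain kernel (avoids the DC
    # bias / cupping of a naive |freq| ramp on a finite window)
    n_pad = int(2 ** np.ceil(np.log2(2 * n_cols)))
    taps = np.zeros(n_pad)
    taps[0] = 0.25
    k = np.arange(1, n_pad // 2 + 1, 2)
    taps[k] = -1.0 / (np.pi * k) ** 2
    taps[-k] = -1.0 / (np.pi * k) ** 2
    filt = 2.0 * np.real(np.fft.fft(taps)) / (2.0 * ds)
    padded = np.zeros((g.n_angles, n_pad))
    padded[:, :n_cols] = vals
    q = np.real(np.fft.ifft(np.fft.fft(padded, axis=1) * filt[None, :], axis=1))
    q = q[:, :n_cols]

    x, y, px = _image_grid(grid_n)
    theta = np.deg2rad(g.angles_deg())
    out = np.zeros((grid_n, grid_n))
    s0 = (0.5 - n_cols / 2) * ds  # offset of column 0
    for k in range(g.n_angles):
        s = x * np.cos(theta[k]) + y * np.sin(theta[k])
        t = (s - s0) / ds  # fractional column index
        t0 = np.floor(t).astype(np.int64)
        frac = t - t0
        t0c = np.clip(t0, 0, n_cols - 1)
        t1c = np.clip(t0 + 1, 0, n_cols - 1)
        inside = (t >= -0.5) & (t <= n_cols - 0.5)
        row = q[k]
        out += np.where(inside, row[t0c] * (1 - frac) + row[t1c] * frac, 0.0)
    out *= np.pi / g.n_angles * np.deg2rad(g.angular_range) / np.pi
    # pixels outside the detector's lateral coverage are unconstrained by the
    # data; zero them (the standard reconstruction circle)
    fov = abs(g.offsets()).max() + ds / 2
    out[x * x + y * y > fov * fov] = 0.0
    return ReconImage(out, px, {"method": "fbp", "filter": "ram-lak"})


# ---------------------------------------------------------------------------
# discrete forward operator (ray marching, bilinear interpolation)

def build_projector(geometry: Geometry, grid_n: int, step_factor: float = 1.0) -> sp.csr_matrix:
    """Sparse matrix mapping an image (flattened) to sinogram line integrals.

    Rays are marched in steps of ``step_factor`` image pixels; at each
    sample the image is read with bilinear interpolation and the sample is
    weighted by the step length, so ``A @ u`` approximates the physical line
    integral and ``A.T`` is its exact adjoint.
    """
    x0, y0, px = _image_grid(grid_n)
    theta = np.deg2rad(geometry.angles_deg())
    offsets = geometry.offsets()
    step = step_factor * px
    half_diag = np.sqrt(2.0)
    n_steps = int(np.ceil(2 * half_diag / step)) + 1
    t = -half_diag + step * np.arange(n_steps)

    rows, cols, data = [], [], []
    n_cols = geometry.n_cols
    for k in range(geometry.n_angles):
        ct, st = np.cos(theta[k]), np.sin(theta[k])
        # ray for offset s: point(tau) = s * (ct, st) + tau * (-st, ct)
        xs = offsets[:, None] * ct - t[None, :] * st  # (n_cols, n_steps)
        ys = offsets[:, None] * st + t[None, :] * ct
        fx = (xs + 1.0) / px - 0.5  # fractional column index
        fy = (ys + 1.0) / px - 0.5  # fractional row index
        ix = np.floor(fx).astype(np.int64)
        iy = np.floor(fy).astype(np.int64)
        wx = fx - ix
        wy = fy - iy
        for dyy in (0, 1):
            for dxx in (0, 1):
                gx = ix + dxx
                gy = iy + dyy
                w = (wx if dxx else 1 - wx) * (wy if dyy else 1 - wy) * step
                ok = (gx >= 0) & (gx < grid_n) & (gy >= 0) & (gy < grid_n) & (w > 0)
                if not ok.any():
                    continue
                det_idx = np.broadcast_to(np.arange(n_cols)[:, None], ok.shape)[ok]
                rows.append(k * n_cols + det_idx)
                cols.append(gy[ok] * grid_n + gx[ok])
                data.append(w[ok])
    A = sp.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(geometry.n_angles * n_cols, grid_n * grid_n),
    )
    return A.tocsr()


def forward_project(image: np.ndarray, geometry: Geometry, pixel_size: float | None = None) -> np.ndarray:
    """Discrete line integrals of an image (builds the projector on the fly)."""
    grid_n = image.shape[0]
    A = build_projector(geometry, grid_n)
    return (A @ image.ravel()).reshape(geometry.n_angles, geometry.n_cols)


def operator_norm(A: sp.csr_matrix, n_iter: int = 20, seed: int = 0) -> float:
    """Largest singular value of A by power iteration on A^T A."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(A.shape[1])
    x /= np.linalg.norm(x)
    for _ in range(n_iter):
        y = A.T @ (A @ x)
        nrm = np.linalg.norm(y)
        if nrm == 0:
            return 0.0
        x = y / nrm
    return float(np.sqrt(nrm))


def _grad(u: np.ndarray) -> np.ndarray:
    """Forward differences with Neumann boundary; returns (2, H, W)."""
    g = np.zeros((2,) + u.shape)
    g[0, :-1, :] = u[1:, :] - u[:-1, :]
    g[1, :, :-1] = u[:, 1:] - u[:, :-1]
    return g


def _div(p: np.ndarray) -> np.ndarray:
    """Negative adjoint of _grad: div p with matching boundary handling."""
    d = np.zeros(p.shape[1:])
    d[:-1, :] += p[0, :-1, :]
    d[1:, :] -= p[0, :-1, :]
    d[:, :-1] += p[1, :, :-1]
    d[:, 1:] -= p[1, :, :-1]
    return d


def tv_reconstruct(sino: Sinogram, grid_n: int, cfg: TVConfig,
                   A: sp.csr_matrix | None = None) -> ReconImage:
    """Chambolle-Pock solver for (1/2)||Au - b||^2 + lambda TV(u)."""
    vals = sino.values
    if not np.all(np.isfinite(vals)):
        raise ValueError("sinogram contains missing entries; complete it first")
    if A is None:
        A = build_projector(sino.geometry, grid_n)
    b = vals.ravel()
    px = 2.0 / grid_n
    lam = cfg.tv_weight

    normA = operator_norm(A)
    # ||K||^2 <= ||A||^2 + 8 for K = [A; grad] with unit-spacing differences
    L = np.sqrt(normA ** 2 + 8.0)
    sigma = cfg.step_ratio * 0.99 / L
    tau = 0.99 / (L * cfg.step_ratio)
    if sigma * tau * L * L > 1.0 + 1e-9:
        raise ValueError("step-size contract sigma*tau*||K||^2 <= 1 violated")

    u = np.zeros(grid_n * grid_n)
    u_bar = u.copy()
    y1 = np.zeros_like(b)
    y2 = np.zeros((2, grid_n, grid_n))

    for _ in range(cfg.n_iterations):
        y1 = (y1 + sigma * (A @ u_bar - b)) / (1.0 + sigma)
        y2 += sigma * _grad(u_bar.reshape(grid_n, grid_n))
        mag = np.sqrt(np.sum(y2 ** 2, axis=0))
        scale = np.maximum(1.0, mag / lam) if lam > 0 else np.maximum(1.0, mag / 1e-30)
        y2 /= scale[None, :, :]
        u_new = u - tau * (A.T @ y1 - _div(y2).ravel())
        u_bar = 2.0 * u_new - u
        u = u_new

    img = u.reshape(grid_n, grid_n)
    resid = A @ u - b
    primal = 0.5 * float(resid @ resid) + lam * float(
        np.sqrt(np.sum(_grad(img) ** 2, axis=0)).sum()
    )
    dual = -0.5 * float(y1 @ y1) - float(b @ y1)
    return ReconImage(img, px, {
        "method": "tv_chambolle_pock", "tv_weight": lam,
        "n_iterations": cfg.n_iterations, "primal_objective": primal,
        "primal_dual_gap": primal - dual, "operator_norm": normA,
    })


def tune_tv_parameter(
    sino: Sinogram, reference: "ReconImage | np.ndarray", metric: str,
    lam_grid, grid_n: int, n_iterations: int = 300,
) -> tuple[float, ReconImage, float]:
    """Reconstruct at every lambda on the grid; return the metric-best.

    ``metric`` is "psnr" or "ms_ssim"; ties break toward smaller lambda.
    Returns (best lambda, best reconstruction, best metric value).
    """
    from .metrics import ms_ssim, psnr

    ref = reference.values if isinstance(reference, ReconImage) else np.asarray(reference)
    lam_grid = sorted(float(l) for l in lam_grid)
    if not lam_grid:
        raise ValueError("empty lambda grid")
    A = build_projector(sino.geometry, grid_n)
    best = None
    for lam in lam_grid:
        rec = tv_reconstruct(sino, grid_n, TVConfig(lam, n_iterations), A=A)
        score = psnr(rec.values, ref) if metric == "psnr" else ms_ssim(rec.values, ref)
        if best is None or score > best[2]:
            best = (lam, rec, score)
    return best
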