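"""Parallel-beam forward projection and the photon-counting noise model.

A sinogram entry is the line integral of attenuation along one ray,
``p = -ln(T)`` with ``T`` the transmittance.  For the sphere-in-cylinder
phantom the integral has a closed form: the chord length of the ray through
the cylinder minus the chord lengths through every intersected void, all
multiplied by mu.  Measurement noise follows transmission counting
statistics: each detector pixel records a Poisson number of photons with
mean ``I0 * exp(-p)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import h5py
import numpy as np
from scipy.optimize import brentq

from .phantom import SphereSet, rasterize_slice


@dataclass(frozen=True)
class Geometry:
    """Parallel-beam acquisition geometry.

    Angles are ``angle_of(k) = k * angular_range / n_angles`` for
    ``k = 0 .. n_angles - 1`` (degrees); detector column ``j`` senses the
    signed lateral offset ``s_j = (j + 0.5 - n_cols / 2) * pixel_size``,
    rotated counter-clockwise by the projection angle.
    """

    n_angles: int = 1024
    n_cols: int = 1024
    angular_range: float = 180.0
    pixel_size: float = 2.0 / 1024

    def __post_init__(self) -> None:
        if self.n_angles < 1 or self.n_cols < 1:
            raise ValueError("n_angles and n_cols must be >= 1")

    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_angles) * (self.angular_range / self.n_angles)

    def angle_of(self, k: int) -> float:
        return k * self.angular_range / self.n_angles

    def offsets(self) -> np.ndarray:
        return (np.arange(self.n_cols) + 0.5 - self.n_cols / 2) * self.pixel_size


@dataclass
class Sinogram:
    """Line integrals on an angles-by-columns grid, with geometry metadata."""

    values: np.ndarray  # (n_angles, n_cols)
    geometry: Geometry
    slice_z: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.geometry.n_angles, self.geometry.n_cols):
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry "
                f"({self.geometry.n_angles}, {self.geometry.n_cols})"
            )

    def copy_with(self, values: np.ndarray) -> "Sinogram":
        return Sinogram(np.array(values), self.geometry, self.slice_z)


@dataclass(frozen=True)
class NoiseModel:
    """Poisson counting noise: I0 incident photons per detector pixel.

    Zero counts are clamped to ``count_floor`` before the log so that fully
    absorbed rays map to a finite, maximal line integral.
    """

    incident_photons: float = 1000.0
    count_floor: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.incident_photons <= 0:
            raise ValueError("incident_photons must be > 0")
        if not (0.0 < self.count_floor <= 1.0):
            raise ValueError("count_floor must be in (0, 1]")


def project_analytic(spheres: SphereSet, geometry: Geometry, z: float = 0.0) -> Sinogram:
    """Closed-form noiseless sinogram of the foam phantom at height ``z``.

    Each entry is mu * (cylinder chord - sum of void chords), using exact
    ray-circle intersections; one infinitesimally thin ray per detector
    column through the column center.
    """
    spec = spheres.spec
    mu = spec.attenuation
    R = spec.cylinder_radius
    s = geometry.offsets()  # (n_cols,)
    theta = np.deg2rad(geometry.angles_deg())  # (n_angles,)

    cyl = 2.0 * np.sqrt(np.maximum(R * R - s * s, 0.0))  # (n_cols,)
    out = np.broadcast_to(cyl, (geometry.n_angles, geometry.n_cols)).copy()

    c, r = spheres.centers, spheres.radii
    dz2 = (z - c[:, 2]) ** 2
    active = dz2 < r ** 2
    if np.any(active):
        cx = c[active, 0]
        cy = c[active, 1]
        rz2 = r[active] ** 2 - dz2[active]  # in-plane radius^2 of each void
        cos_t = np.cos(theta)[:, None]  # (n_angles, 1)
        sin_t = np.sin(theta)[:, None]
        # signed distance of sphere center from each ray: d = c . n - s
        proj = cx[None, :] * cos_t + cy[None, :] * sin_t  # (n_angles, n_act)
        d2 = (proj[:, :, None] - s[None, None, :]) ** 2  # (n_angles, n_act, n_cols)
        chord = 2.0 * np.sqrt(np.maximum(rz2[None, :, None] - d2, 0.0))
        out -= chord.sum(axis=1)

    return Sinogram(mu * np.maximum(out, 0.0), geometry, slice_z=z)


def project_voxelized(
    spheres: SphereSet, geometry: Geometry, z: float = 0.0, grid_n: int = 512,
    supersample: int = 2,
) -> Sinogram:
    """Discrete alternative projector: Radon transform of a rasterized slice.

    Rasterizes the slice at ``grid_n`` and applies the package's discrete
    line-integral operator.  Slower and subject to discretization error;
    the analytic form is the reference.
    """
    from .reconstruct import forward_project

    sl = rasterize_slice(spheres, z, grid_n, supersample=supersample)
    vals = forward_project(sl.values, geometry, sl.pixel_size)
    return Sinogram(vals, geometry, slice_z=z)


def calibrate_attenuation(
    spheres: SphereSet, geometry: Geometry, target_absorption: float, z: float = 0.0,
    tol: float = 1e-4,
) -> float:
    """Attenuation mu at which the sample absorbs ``target_absorption`` of photons.

    Solves ``mean_j(1 - exp(-mu * l_j)) = target_absorption`` over the
    sinogram entries, where ``l_j`` are the unit-mu path lengths, by a
    monotone scalar root-find.
    """
    if not (0.0 < target_absorption < 1.0):
        raise ValueError("target_absorption must be in (0, 1)")
    unit = replace(spheres.spec, attenuation=1.0)
    lengths = project_analytic(
        SphereSet(spheres.centers, spheres.radii, unit), geometry, z
    ).values
    if not np.any(lengths > 0):
        raise ValueError("phantom contains no material along any ray")

    def absorbed(mu: float) -> float:
        return float(np.mean(1.0 - np.exp(-mu * lengths))) - target_absorption

    hi = 1.0
    while absorbed(hi) < 0:
        hi *= 2.0
        if hi > 1e9:
            raise RuntimeError("calibration failed to bracket the root")
    return float(brentq(absorbed, 0.0, hi, xtol=tol * 1e-2, rtol=1e-12))


def apply_counting_noise(sino: Sinogram, noise: NoiseModel) -> Sinogram:
    """Draw Poisson photon counts and return the noisy line integrals.

    ``counts ~ Poisson(I0 * exp(-p))`` independently per entry; the returned
    values are ``-ln(max(counts, count_floor) / I0)``.  Deterministic for a
    fixed seed.
    """
    if np.any(sino.values < 0) or not np.all(np.isfinite(sino.values)):
        raise ValueError("input sinogram must be noiseless: finite, >= 0")
    rng = np.random.default_rng(noise.seed)
    expected = noise.incident_photons * np.exp(-sino.values)
    counts = rng.poisson(expected).astype(np.float64)
    counts = np.maximum(counts, noise.count_floor)
    return sino.copy_with(-np.log(counts / noise.incident_photons))


# ---------------------------------------------------------------------------
# persistence

def save_sinogram(path: str, sino: Sinogram, **extra_attrs) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("sino", data=sino.values, track_times=False)
        g = sino.geometry
        d.attrs.update(
            n_angles=g.n_angles, n_cols=g.n_cols,
            angular_range=g.angular_range, pixel_size=g.pixel_size,
            slice_z=sino.slice_z,
        )
        d.attrs.update(extra_attrs)


def load_sinogram(path: str) -> Sinogram:
    with h5py.File(path, "r") as f:
        d = f["sino"]
        a = d.attrs
        geom = Geometry(
            n_angles=int(a["n_angles"]), n_cols=int(a["n_cols"]),
            angular_range=float(a["angular_range"]), pixel_size=float(a["pixel_size"]),
        )
        return Sinogram(d[()], geom, slice_z=float(a["slice_z"]))
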