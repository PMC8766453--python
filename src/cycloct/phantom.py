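"""Numerical foam phantom: non-overlapping spherical voids in a uniform cylinder.

The sample emulated throughout the package is a cylinder of a single
homogeneous material from which randomly placed, non-overlapping spheres of
varying sizes have been removed.  The combination of large- and fine-scale
voids makes the object a demanding benchmark for tomographic reconstruction.

Coordinates: the field of view is the square [-1, 1]^2 in (x, y); the
cylinder axis is the z-axis.  Pixel (0, 0) of a rasterized slice is the
corner pixel, pixel centers sit at -1 + (j + 0.5) * pixel_size.  All indices
are 0-based.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import h5py
import numpy as np
import tifffile


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and material of the foam sample.

    Parameters
    ----------
    cylinder_radius : float
        Radius of the bulk cylinder as a fraction of the half field of view.
    n_spheres : int
        Number of spherical voids to remove.
    radius_min, radius_max : float
        Bounds of the void-radius distribution (field-of-view units).
    radius_exponent : float
        Shape parameter of the size distribution: radii are drawn as
        ``r = radius_min * (radius_max/radius_min) ** (u ** radius_exponent)``
        with ``u ~ Uniform(0, 1)``.  Larger exponents give many small and few
        large voids, mimicking real foams.
    attenuation : float
        Linear attenuation coefficient mu of the bulk material
        (inverse field-of-view units).
    seed : int
        Seed for the sphere placement RNG.
    """

    cylinder_radius: float = 0.8
    n_spheres: int = 500
    radius_min: float = 0.01
    radius_max: float = 0.15
    radius_exponent: float = 3.0
    attenuation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.radius_min <= self.radius_max < self.cylinder_radius):
            raise ValueError(
                "require 0 < radius_min <= radius_max < cylinder_radius, got "
                f"{self.radius_min}, {self.radius_max}, {self.cylinder_radius}"
            )
        if self.n_spheres < 0:
            raise ValueError("n_spheres must be >= 0")
        if self.attenuation <= 0:
            raise ValueError("attenuation must be > 0")


@dataclass
class SphereSet:
    """Centers and radii of the non-overlapping voids of one phantom."""

    centers: np.ndarray  # (n, 3) float64, columns x, y, z
    radii: np.ndarray  # (n,) float64
    spec: PhantomSpec

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=np.float64).reshape(-1)
        if self.centers.shape[0] != self.radii.shape[0]:
            raise ValueError("centers and radii length mismatch")

    def __len__(self) -> int:
        return self.radii.shape[0]

    def validate(self) -> None:
        """Assert non-overlap and lateral containment for every sphere."""
        c, r = self.centers, self.radii
        lateral = np.hypot(c[:, 0], c[:, 1])
        if np.any(lateral + r > self.spec.cylinder_radius + 1e-12):
            raise AssertionError("sphere protrudes from the cylinder")
        if len(self) > 1:
            d = np.linalg.norm(c[None, :, :] - c[:, None, :], axis=-1)
            need = r[None, :] + r[:, None]
            np.fill_diagonal(d, np.inf)
            if np.any(d < need - 1e-12):
                raise AssertionError("overlapping spheres")


@dataclass
class VoxelSlice:
    """One rasterized axial slice of attenuation values."""

    values: np.ndarray  # (grid_n, grid_n) float
    pixel_size: float
    z: float


class PackingError(RuntimeError):
    """Raised when rejection sampling cannot place all requested spheres."""


def generate_phantom(spec: PhantomSpec, max_attempts_per_sphere: int = 10_000) -> SphereSet:
    """Place ``spec.n_spheres`` non-overlapping void spheres inside the cylinder.

    Radii are drawn first from the log-power-law of the spec and inserted
    largest-first by rejection sampling, uniform in cylinder volume, which
    eases packing at high void fractions.  Deterministic for a given seed.

    Raises
    ------
    PackingError
        If a sphere cannot be placed within ``max_attempts_per_sphere``
        rejection draws (packing too dense).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_spheres
    if n == 0:
        return SphereSet(np.empty((0, 3)), np.empty((0,)), spec)

    u = rng.random(n)
    radii = spec.radius_min * (spec.radius_max / spec.radius_min) ** (
        u ** spec.radius_exponent
    )
    radii = np.sort(radii)[::-1]  # largest first

    R = spec.cylinder_radius
    centers = np.empty((n, 3))
    placed = 0
    for i in range(n):
        r = radii[i]
        ok = False
        for _ in range(max_attempts_per_sphere):
            # uniform in the admissible cylinder volume for this radius
            rho = (R - r) * np.sqrt(rng.random())
            phi = 2.0 * np.pi * rng.random()
            zmax = 1.0 - r
            z = rng.uniform(-zmax, zmax)
            cand = np.array([rho * np.cos(phi), rho * np.sin(phi), z])
            if placed:
                d2 = np.sum((centers[:placed] - cand) ** 2, axis=1)
                if np.any(d2 < (radii[:placed] + r) ** 2):
                    continue
            centers[i] = cand
            ok = True
            break
        if not ok:
            raise PackingError(
                f"could not place sphere {i + 1}/{n} (radius {r:.4g}) after "
                f"{max_attempts_per_sphere} attempts; reduce n_spheres or radii"
            )
        placed += 1

    out = SphereSet(centers, radii, spec)
    out.validate()
    return out


def _inside_material(spheres: SphereSet, x: np.ndarray, y: np.ndarray, z: float) -> np.ndarray:
    """Boolean mask: points inside the cylinder and outside all voids at height z."""
    spec = spheres.spec
    inside = (x * x + y * y) <= spec.cylinder_radius ** 2
    c, r = spheres.centers, spheres.radii
    dz2 = (z - c[:, 2]) ** 2
    active = dz2 < r ** 2
    for cx, cy, rz2 in zip(c[active, 0], c[active, 1], r[active] ** 2 - dz2[active]):
        inside &= (x - cx) ** 2 + (y - cy) ** 2 > rz2
    return inside


def rasterize_slice(
    spheres: SphereSet, z: float, grid_n: int, supersample: int = 4
) -> VoxelSlice:
    """Rasterize the attenuation map of the axial slice at height ``z``.

    Each pixel value is mu times the area fraction of the pixel lying inside
    the cylinder and outside every void, estimated with ``supersample**2``
    uniformly spaced subsamples per pixel.
    """
    if grid_n < 1 or supersample < 1:
        raise ValueError("grid_n and supersample must be >= 1")
    spec = spheres.spec
    fine_n = grid_n * supersample
    px_fine = 2.0 / fine_n
    coords = -1.0 + (np.arange(fine_n) + 0.5) * px_fine
    x, y = np.meshgrid(coords, coords, indexing="xy")
    mask = _inside_material(spheres, x, y, z).astype(np.float64)
    # block-average supersample x supersample cells
    frac = mask.reshape(grid_n, supersample, grid_n, supersample).mean(axis=(1, 3))
    return VoxelSlice(values=spec.attenuation * frac, pixel_size=2.0 / grid_n, z=z)


# ---------------------------------------------------------------------------
# persistence

def save_spheres(path: str, spheres: SphereSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("centers", data=spheres.centers, track_times=False)
        f.create_dataset("radii", data=spheres.radii, track_times=False)
        for k, v in dataclasses.asdict(spheres.spec).items():
            f.attrs[k] = v


def load_spheres(path: str) -> SphereSet:
    with h5py.File(path, "r") as f:
        centers = f["centers"][()]
        radii = f["radii"][()]
        attrs = {k: f.attrs[k] for k in f.attrs}
    attrs["n_spheres"] = int(attrs["n_spheres"])
    attrs["seed"] = int(attrs["seed"])
    return SphereSet(centers, radii, PhantomSpec(**attrs))


def save_slice(path: str, sl: VoxelSlice) -> None:
    tifffile.imwrite(path, sl.values.astype(np.float32))
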