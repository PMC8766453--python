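"""Shared fixtures: small phantoms, geometries, and the one desk-scale run.

The expensive session fixture ``tiny_results`` runs the full dose-reduction
benchmark at the desk-scale preset once; the acceptance tests that check
method orderings and training behaviour all read from it.
"""

from dataclasses import replace

import numpy as np
import pytest

from cycloct import (
    Geometry, PhantomSpec, SphereSet, generate_phantom,
)
from cycloct.pipeline import ExperimentConfig, tiny_config, derive_seed
from cycloct.msd_network import MSDConfig
from cycloct.training import TrainConfig


@pytest.fixture(scope="session")
def foam20():
    """20-void phantom used by projection and reconstruction tests."""
    spec = PhantomSpec(n_spheres=20, radius_min=0.05, radius_max=0.2,
                       attenuation=2.0, seed=5)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def empty_cylinder():
    """Uniform disk (no voids), radius 0.6, mu = 1."""
    spec = PhantomSpec(n_spheres=0, attenuation=1.0, cylinder_radius=0.6)
    return SphereSet(np.empty((0, 3)), np.empty(0), spec)


@pytest.fixture
def geom128():
    return Geometry(n_angles=128, n_cols=128, pixel_size=2.0 / 128)


def micro_config(seed: int = 0, **overrides) -> ExperimentConfig:
    """Very small end-to-end configuration for fast pipeline tests."""
    cfg = ExperimentConfig(
        phantom=PhantomSpec(n_spheres=16, radius_min=0.03, radius_max=0.2,
                            seed=derive_seed(seed, "phantom")),
        geometry=Geometry(n_angles=64, n_cols=64, pixel_size=2.0 / 64),
        n_train=5, n_slices=6,
        msd=MSDConfig(depth=5, dilation_cycle=(1, 2, 3),
                      seed=derive_seed(seed, "init")),
        train=TrainConfig(max_epochs=2, seed=derive_seed(seed, "shuffle")),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


@pytest.fixture(scope="session")
def tiny_results():
    """Full desk-scale benchmark: four methods sharing one phantom and noise.

    Returns (reports, artifacts) from run_comparison on the tiny preset.
    """
    from cycloct.pipeline import run_comparison

    cfg = tiny_config(seed=1)
    reports, artifacts = run_comparison(cfg)
    return {r.method: r for r in reports}, artifacts
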