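"""End-to-end experiment orchestration and the dose-reduction benchmark.

The central experiment: simulate a foam sample scanned with a masked beam,
compare dose-reduction strategies on the central slice, and for the
cycloidal strategy train the sinogram-completion network with training data
generated *within* the scan itself (a few fully dithered projections
interleaved with the cycloidal ones).

The cycloidal chain is: phantom -> analytic projection -> counting noise ->
acquisition mask -> bicubic completion -> network training on the partial
sinograms -> network application -> FBP -> metrics.  All compared methods
share the same phantom and, where exposure matches, the same noise
realization, so differences between rows are due to the sampling strategy
alone.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .forward_model import (
    Geometry, NoiseModel, Sinogram, apply_counting_noise, calibrate_attenuation,
    project_analytic,
)
from .inpaint import bicubic_interpolate
from .metrics import MetricReport, dice, ms_ssim, psnr, threshold_segment, write_report_csv
from .msd_network import MSDConfig, MSDModel, load_model, save_model
from .phantom import PhantomSpec, SphereSet, generate_phantom, rasterize_slice
from .reconstruct import ReconImage, TVConfig, fbp, tune_tv_parameter
from .sampling import (
    AcquisitionPlan, PartialSinogram, SamplingPattern, apply_pattern, build_mask,
    dose_fraction, extract_partial, select_training_angles,
)
from .training import TrainConfig, TrainingSet, TrainLog, apply_model, train

#: methods understood by run_comparison
KNOWN_METHODS = (
    "complete",
    "low_exposure", "low_exposure_tv", "low_exposure_msd",
    "angular", "angular_bicubic", "angular_tv",
    "cycloidal_bicubic", "cycloidal_msd",
)

_STAGE_SEEDS = {"phantom": 1, "noise": 2, "init": 3, "shuffle": 4, "split": 5,
                "noise_low": 6}


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed so changing one stage leaves others unchanged."""
    ss = np.random.SeedSequence([int(global_seed), _STAGE_SEEDS[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class ExperimentConfig:
    """Everything needed for one benchmark run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    geometry: Geometry = field(default_factory=Geometry)
    incident_photons: float = 1000.0
    target_absorption: float = 0.5
    period: int = 8
    aperture: int = 1
    shift_per_angle: int = 3
    angular_step_keep: int = 8
    exposure_fraction: float = 0.125
    n_train: int = 33
    n_slices: int = 32
    z_extent: float = 0.3
    msd: MSDConfig = field(default_factory=MSDConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    tv: TVConfig = field(default_factory=TVConfig)
    tv_lambda_grid: tuple[float, ...] = (1e-4, 3e-4, 1e-3, 3e-3, 1e-2)
    methods: tuple[str, ...] = (
        "complete", "angular_bicubic", "cycloidal_bicubic", "cycloidal_msd",
    )
    grid_n: int = 0  # 0 -> geometry.n_cols
    supersample: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for m in self.methods:
            if m not in KNOWN_METHODS:
                raise ValueError(f"unknown method {m!r}")
        if self.grid_n == 0:
            self.grid_n = self.geometry.n_cols

    def slice_zs(self) -> np.ndarray:
        n = self.n_slices
        return (np.arange(n) - n // 2) / max(n, 1) * (2.0 * self.z_extent)

    def central_index(self) -> int:
        return self.n_slices // 2

    def plan_for(self, method: str) -> AcquisitionPlan:
        """Acquisition plan (and hence dose) of one compared method."""
        common = dict(period=self.period, aperture=self.aperture)
        if method == "complete":
            return AcquisitionPlan(mode="dithered", **common)
        if method.startswith("low_exposure"):
            n_train = self.n_train if method == "low_exposure_msd" else 0
            return AcquisitionPlan(mode="low_exposure",
                                   exposure_fraction=self.exposure_fraction,
                                   n_train=n_train, **common)
        if method.startswith("angular"):
            return AcquisitionPlan(mode="angular_subsampled",
                                   angular_step_keep=self.angular_step_keep, **common)
        if method.startswith("cycloidal"):
            n_train = self.n_train if method == "cycloidal_msd" else 0
            return AcquisitionPlan(mode="cycloidal",
                                   shift_per_angle=self.shift_per_angle,
                                   n_train=n_train, **common)
        raise ValueError(method)

    # --- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key, sub in (("phantom", PhantomSpec), ("geometry", Geometry),
                         ("msd", MSDConfig), ("train", TrainConfig),
                         ("tv", TVConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        for key in ("tv_lambda_grid", "methods"):
            if key in d:
                d[key] = tuple(d[key])
        if "msd" in d and isinstance(d["msd"], MSDConfig):
            pass
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        d = self.to_dict()
        d["msd"]["dilation_cycle"] = list(d["msd"]["dilation_cycle"])
        d["tv_lambda_grid"] = list(d["tv_lambda_grid"])
        d["methods"] = list(d["methods"])
        with open(path, "w") as f:
            yaml.safe_dump(d, f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as f:
            d = yaml.safe_load(f)
        if "msd" in d and "dilation_cycle" in d["msd"]:
            d["msd"]["dilation_cycle"] = tuple(d["msd"]["dilation_cycle"])
        return cls.from_dict(d)


def tiny_config(seed: int = 0) -> ExperimentConfig:
    """Desk-scale preset: 128^2 phantom, 128 angles, depth-30 network.

    A scaled-down version of the full simulation study (1024^2 detector,
    1024 angles, depth-100 network) that preserves the mask geometry
    (period 8, aperture 1, shift 3), the photon budget (1000 photons/pixel,
    ~50% absorption) and the evenly spread in-scan training projections.
    """
    return ExperimentConfig(
        phantom=PhantomSpec(cylinder_radius=0.8, n_spheres=500,
                            radius_min=0.01, radius_max=0.15,
                            radius_exponent=3.0, attenuation=1.0,
                            seed=derive_seed(seed, "phantom")),
        geometry=Geometry(n_angles=128, n_cols=128, angular_range=180.0,
                          pixel_size=2.0 / 128),
        incident_photons=1000.0,
        target_absorption=0.5,
        n_train=13,
        n_slices=32,
        msd=MSDConfig(depth=30, dilation_cycle=tuple(range(1, 11)),
                      seed=derive_seed(seed, "init")),
        train=TrainConfig(learning_rate=0.001, train_fraction=0.9,
                          max_epochs=40, max_seconds=600.0,
                          seed=derive_seed(seed, "shuffle")),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# simulation of the shared raw data

@dataclass
class SimulatedScan:
    """Shared raw data consumed by every compared method."""

    spheres: SphereSet
    mu: float
    noiseless: list[Sinogram]
    noisy_full: list[Sinogram]  # full exposure counting noise
    noisy_low: list[Sinogram] | None
    ground_truth: np.ndarray  # central slice attenuation map


def simulate_scan(config: ExperimentConfig, need_low_exposure: bool = False) -> SimulatedScan:
    """Generate the phantom, calibrate mu, project all slices, add noise."""
    spec = replace(config.phantom, attenuation=1.0)
    spheres = generate_phantom(spec)
    mu = calibrate_attenuation(spheres, config.geometry, config.target_absorption)
    spheres = SphereSet(spheres.centers, spheres.radii,
                        replace(spec, attenuation=mu))

    zs = config.slice_zs()
    noiseless = [project_analytic(spheres, config.geometry, z) for z in zs]

    noise_seed = derive_seed(config.seed, "noise")
    noisy_full = [
        apply_counting_noise(s, NoiseModel(config.incident_photons,
                                           seed=noise_seed + i))
        for i, s in enumerate(noiseless)
    ]
    noisy_low = None
    if need_low_exposure:
        low_seed = derive_seed(config.seed, "noise_low")
        noisy_low = [
            apply_counting_noise(
                s, NoiseModel(config.incident_photons * config.exposure_fraction,
                              seed=low_seed + i))
            for i, s in enumerate(noiseless)
        ]

    gt = rasterize_slice(spheres, zs[config.central_index()], config.grid_n,
                         config.supersample).values
    return SimulatedScan(spheres, mu, noiseless, noisy_full, noisy_low, gt)


# ---------------------------------------------------------------------------
# the cycloidal chain (Fig.-3-style pipeline)

@dataclass
class CycloidalArtifacts:
    pattern: SamplingPattern
    interpolated: list[np.ndarray]
    partials: list[PartialSinogram]
    model: MSDModel
    log: TrainLog
    restored: list[np.ndarray]


def run_cycloidal_chain(config: ExperimentConfig, scan: SimulatedScan) -> CycloidalArtifacts:
    """Mask -> interpolate -> train on partial sinograms -> apply."""
    g = config.geometry
    cyc_plan = AcquisitionPlan(mode="cycloidal", period=config.period,
                               aperture=config.aperture,
                               shift_per_angle=config.shift_per_angle)
    pattern = build_mask(cyc_plan, g.n_angles, g.n_cols)
    training_angles = select_training_angles(g.n_angles, config.n_train)

    interpolated = [
        bicubic_interpolate(apply_pattern(s, pattern), pattern).values
        for s in scan.noisy_full
    ]
    partials = [extract_partial(s, training_angles) for s in scan.noisy_full]

    trainset = TrainingSet(inputs=interpolated, targets=partials)
    model, log = train(config.msd, None, trainset, config.train)
    restored = apply_model(model, interpolated)
    return CycloidalArtifacts(pattern, interpolated, partials, model, log, restored)


def _evaluate(name: str, recon: np.ndarray, config: ExperimentConfig,
              scan: SimulatedScan, extra: str = "") -> MetricReport:
    gt = scan.ground_truth
    seg_t = scan.mu / 2.0
    rep = MetricReport(
        method=name,
        dose_percent=dose_fraction(config.plan_for(name), config.geometry.n_angles),
        psnr_db=psnr(recon, gt),
        dice=dice(threshold_segment(recon, "fixed", threshold=seg_t),
                  threshold_segment(gt, "fixed", threshold=seg_t)),
        ms_ssim=ms_ssim(recon, gt),
        parameters=extra or f"threshold=mu/2={seg_t:.4g}",
    )
    return rep


def _reduced_angular(sino: Sinogram, keep: int) -> Sinogram:
    """Sparse-view sinogram: only every ``keep``-th projection, as its own scan."""
    g = sino.geometry
    kept = sino.values[::keep]
    geom = Geometry(n_angles=kept.shape[0], n_cols=g.n_cols,
                    angular_range=g.angular_range, pixel_size=g.pixel_size)
    return Sinogram(kept, geom, sino.slice_z)


def run_comparison(config: ExperimentConfig,
                   output_dir: str | None = None) -> tuple[list[MetricReport], dict]:
    """Benchmark the configured dose-reduction methods on one shared phantom.

    Returns the per-method metric rows (Table-1 analogue) plus a dict of
    intermediate artifacts for inspection.  All methods see the same
    phantom and noiseless data; full-exposure methods share one noise
    realization, low-exposure methods draw fresh counts at reduced photon
    count (a reduced exposure cannot share photons with a full one).
    """
    need_low = any(m.startswith("low_exposure") for m in config.methods)
    scan = simulate_scan(config, need_low_exposure=need_low)
    ci = config.central_index()
    g = config.geometry
    grid_n = config.grid_n
    reports: list[MetricReport] = []
    artifacts: dict = {"scan": scan}

    cyc: CycloidalArtifacts | None = None
    if any(m.startswith("cycloidal") for m in config.methods):
        need_net = "cycloidal_msd" in config.methods
        if need_net:
            cyc = run_cycloidal_chain(config, scan)
        else:
            cyc_plan = AcquisitionPlan(mode="cycloidal", period=config.period,
                                       aperture=config.aperture,
                                       shift_per_angle=config.shift_per_angle)
            pattern = build_mask(cyc_plan, g.n_angles, g.n_cols)
            interp = [bicubic_interpolate(
                apply_pattern(scan.noisy_full[ci], pattern), pattern).values]
            cyc = CycloidalArtifacts(pattern, interp, [], None, None, [])  # type: ignore
        artifacts["cycloidal"] = cyc

    central_full = scan.noisy_full[ci]

    for method in config.methods:
        if method == "complete":
            rec = fbp(central_full, grid_n).values
            reports.append(_evaluate(method, rec, config, scan))
        elif method == "low_exposure":
            rec = fbp(scan.noisy_low[ci], grid_n).values
            reports.append(_evaluate(method, rec, config, scan))
        elif method == "low_exposure_tv":
            lam, recimg, _ = tune_tv_parameter(
                scan.noisy_low[ci], scan.ground_truth, "psnr",
                config.tv_lambda_grid, grid_n, config.tv.n_iterations)
            reports.append(_evaluate(method, recimg.values, config, scan,
                                     extra=f"tv_weight={lam:g}"))
        elif method == "low_exposure_msd":
            rec = _low_exposure_denoise(config, scan, grid_n)
            reports.append(_evaluate(method, rec, config, scan))
        elif method == "angular":
            rec = fbp(_reduced_angular(central_full, config.angular_step_keep),
                      grid_n).values
            reports.append(_evaluate(method, rec, config, scan))
        elif method == "angular_tv":
            lam, recimg, _ = tune_tv_parameter(
                _reduced_angular(central_full, config.angular_step_keep),
                scan.ground_truth, "psnr", config.tv_lambda_grid, grid_n,
                config.tv.n_iterations)
            reports.append(_evaluate(method, recimg.values, config, scan,
                                     extra=f"tv_weight={lam:g}"))
        elif method == "angular_bicubic":
            plan = config.plan_for(method)
            pattern = build_mask(plan, g.n_angles, g.n_cols)
            interp = bicubic_interpolate(
                apply_pattern(central_full, pattern), pattern)
            rec = fbp(interp, grid_n).values
            reports.append(_evaluate(method, rec, config, scan))
        elif method == "cycloidal_bicubic":
            rec = fbp(central_full.copy_with(cyc.interpolated[ci if cyc.restored else 0]),
                      grid_n).values
            reports.append(_evaluate(method, rec, config, scan))
        elif method == "cycloidal_msd":
            rec = fbp(central_full.copy_with(cyc.restored[ci]), grid_n).values
            reports.append(_evaluate(method, rec, config, scan))

    if output_dir:
        os.makedirs(output_dir, exist_ok=True)
        write_report_csv(os.path.join(output_dir, "comparison.csv"), reports)
        if cyc is not None and cyc.model is not None:
            save_model(os.path.join(output_dir, "model.h5"), cyc.model)
            cyc.log.to_csv(os.path.join(output_dir, "training_log.csv"))
        with open(os.path.join(output_dir, "provenance.json"), "w") as f:
            json.dump({"seed": config.seed, "mu": scan.mu,
                       "methods": list(config.methods)}, f, indent=2)
    return reports, artifacts


def _low_exposure_denoise(config: ExperimentConfig, scan: SimulatedScan,
                          grid_n: int) -> np.ndarray:
    """Projection-denoising baseline reusing the same training machinery.

    Inputs are the low-exposure sinograms; targets are partial sinograms
    holding the full-exposure training projections.
    """
    g = config.geometry
    training_angles = select_training_angles(g.n_angles, config.n_train)
    inputs = [s.values for s in scan.noisy_low]
    targets = [extract_partial(s, training_angles) for s in scan.noisy_full]
    model, _ = train(config.msd, None, TrainingSet(inputs, targets), config.train)
    ci = config.central_index()
    den = model.predict(scan.noisy_low[ci].values)
    return fbp(scan.noisy_low[ci].copy_with(den), grid_n).values


# ---------------------------------------------------------------------------
# persisted, resumable single-method pipeline

def run_cycloidal_pipeline(config: ExperimentConfig, output_dir: str,
                           resume: bool = True) -> MetricReport:
    """Cycloidal chain with every intermediate persisted; resumable.

    Stages write their artifacts into ``output_dir``; with ``resume=True``
    a stage whose artifact already exists is loaded instead of recomputed,
    so deleting downstream files and rerunning reproduces them.
    """
    from .forward_model import load_sinogram, save_sinogram

    os.makedirs(output_dir, exist_ok=True)
    path = lambda name: os.path.join(output_dir, name)
    g = config.geometry
    ci = config.central_index()

    scan = simulate_scan(config)

    # stage: interpolated + partial sinograms
    cyc_plan = AcquisitionPlan(mode="cycloidal", period=config.period,
                               aperture=config.aperture,
                               shift_per_angle=config.shift_per_angle)
    pattern = build_mask(cyc_plan, g.n_angles, g.n_cols)
    training_angles = select_training_angles(g.n_angles, config.n_train)

    interp_paths = [path(f"interp_{i:04d}.h5") for i in range(config.n_slices)]
    if resume and all(os.path.exists(p) for p in interp_paths):
        interpolated = [load_sinogram(p).values for p in interp_paths]
    else:
        interpolated = []
        for i, s in enumerate(scan.noisy_full):
            v = bicubic_interpolate(apply_pattern(s, pattern), pattern).values
            save_sinogram(interp_paths[i], s.copy_with(v))
            interpolated.append(v)
    partials = [extract_partial(s, training_angles) for s in scan.noisy_full]

    # stage: training
    model_path = path("model.h5")
    if resume and os.path.exists(model_path):
        model = load_model(model_path)
    else:
        model, log = train(config.msd, None,
                           TrainingSet(interpolated, partials), config.train)
        save_model(model_path, model)
        log.to_csv(path("training_log.csv"))

    # stage: apply + reconstruct central slice
    restored = model.predict(interpolated[ci])
    rec = fbp(scan.noisy_full[ci].copy_with(restored), config.grid_n)

    import tifffile
    tifffile.imwrite(path("recon_central.tif"), rec.values.astype(np.float32))

    rep = _evaluate("cycloidal_msd", rec.values, config, scan)
    write_report_csv(path("metrics.csv"), [rep])
    return rep


# ---------------------------------------------------------------------------
# miniature deterministic fixture bundle for the test suite

def generate_fixtures(seed: int, output_dir: str) -> dict:
    """Write a deterministic miniature dataset used by the test suite.

    16-sphere phantom, 64x64 sinograms over 64 angles, every acquisition
    mask, and a depth-5 checkpoint trained for two epochs, with its
    validation loss recorded for replay checks.
    """
    os.makedirs(output_dir, exist_ok=True)
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
    scan = simulate_scan(cfg)
    from .phantom import save_spheres
    from .forward_model import save_sinogram

    save_spheres(os.path.join(output_dir, "phantom.h5"), scan.spheres)
    save_sinogram(os.path.join(output_dir, "sino_central.h5"),
                  scan.noisy_full[cfg.central_index()])

    import tifffile
    for mode in ("dithered", "cycloidal", "rotation_only", "angular_subsampled"):
        plan = AcquisitionPlan(mode=mode, period=8, aperture=1, shift_per_angle=3)
        mask = build_mask(plan, 64, 64).mask
        tifffile.imwrite(os.path.join(output_dir, f"mask_{mode}.tif"),
                         mask.astype(np.uint8))

    art = run_cycloidal_chain(cfg, scan)
    save_model(os.path.join(output_dir, "checkpoint.h5"), art.model)
    art.log.to_csv(os.path.join(output_dir, "training_log.csv"))
    cfg.to_yaml(os.path.join(output_dir, "config.yaml"))
    return {"config": cfg, "scan": scan, "artifacts": art}
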