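"""Acquisition masks for masked-beam CT scans and dose accounting.

A beam-shaping mask with period ``p`` pixels and aperture width ``w`` pixels
lets through ``w`` out of every ``p`` detector columns per frame.  Scan
modes:

- ``dithered``: the sample is step-scanned laterally at each angle so every
  column is eventually sampled — a complete sinogram at full dose
  (p/w frames per angle).
- ``cycloidal``: the sample translates by ``shift_per_angle`` pixels between
  consecutive projections while rotating, so each angle samples a different
  column residue of the mask period — an interlaced, incomplete sinogram at
  one frame per angle.
- ``rotation_only``: cycloidal with zero shift; every angle samples the same
  columns.
- ``angular_subsampled``: full (dithered) rows, but only every k-th angle
  kept.
- ``low_exposure``: complete sampling at a reduced exposure per frame.

A few *training* angles may be interleaved: at those angles full dithering
is applied, giving completely sampled rows that later serve as training
targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .forward_model import Sinogram

MODES = ("dithered", "cycloidal", "rotation_only", "angular_subsampled", "low_exposure")


@dataclass(frozen=True)
class AcquisitionPlan:
    """Mask geometry and scan strategy for one acquisition."""

    mode: str = "cycloidal"
    period: int = 8
    aperture: int = 1
    shift_per_angle: int = 3
    initial_offset: int = 0
    angular_step_keep: int = 8
    exposure_fraction: float = 1.0
    n_train: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if not (1 <= self.aperture <= self.period):
            raise ValueError("require 1 <= aperture <= period")
        if not (0 <= self.shift_per_angle < self.period):
            raise ValueError("require 0 <= shift_per_angle < period")
        if not (0 <= self.initial_offset < self.period):
            raise ValueError("require 0 <= initial_offset < period")
        if self.angular_step_keep < 1:
            raise ValueError("angular_step_keep must be >= 1")
        if not (0.0 < self.exposure_fraction <= 1.0):
            raise ValueError("exposure_fraction must be in (0, 1]")
        if self.n_train < 0:
            raise ValueError("n_train must be >= 0")
        ratio = self.period / self.aperture
        if self.mode in ("cycloidal", "rotation_only") and not (3.0 <= ratio <= 10.0):
            warnings.warn(
                f"aperture:period ratio 1:{ratio:g} is outside the usual 1:3 to 1:10 "
                "masked-beam regime", stacklevel=2,
            )


@dataclass
class SamplingPattern:
    """Boolean acquisition mask over sinogram entries plus its plan."""

    mask: np.ndarray  # (n_angles, n_cols) bool, True = acquired
    plan: AcquisitionPlan
    training_angles: list[int] = field(default_factory=list)


@dataclass
class PartialSinogram:
    """A sinogram defined only on fully sampled (training) rows.

    ``values`` carries NaN at undefined entries; ``defined`` is the source
    of truth for which pixels hold measurements.
    """

    values: np.ndarray
    defined: np.ndarray  # bool, True only on training-angle rows

    def __post_init__(self) -> None:
        if self.values.shape != self.defined.shape:
            raise ValueError("values/defined shape mismatch")


def select_training_angles(n_angles: int, n_train: int) -> list[int]:
    """Indices of ``n_train`` projections distributed evenly over the range.

    Uses ``round(i * n_angles / n_train)`` clamped to the valid range;
    evenly spreading the training projections over the angular range is the
    arrangement that works best for in-scan training.
    """
    if not (0 <= n_train <= n_angles):
        raise ValueError("require 0 <= n_train <= n_angles")
    if n_train == 0:
        return []
    idx = [min(round(i * n_angles / n_train), n_angles - 1) for i in range(n_train)]
    # rounding can only collide for n_train close to n_angles; dedupe upward
    out: list[int] = []
    for k in idx:
        while k in out:
            k += 1
        out.append(k)
    return sorted(out)


def build_mask(plan: AcquisitionPlan, n_angles: int, n_cols: int) -> SamplingPattern:
    """Construct the boolean acquisition mask for a scan plan.

    Cycloidal rows satisfy ``(j - initial_offset - k * shift) mod p < w``;
    training rows (and all rows of complete modes) are entirely True.
    """
    p, w = plan.period, plan.aperture
    train = select_training_angles(n_angles, plan.n_train)
    j = np.arange(n_cols)

    if plan.mode in ("dithered", "low_exposure"):
        mask = np.ones((n_angles, n_cols), dtype=bool)
    elif plan.mode == "angular_subsampled":
        mask = np.zeros((n_angles, n_cols), dtype=bool)
        mask[::plan.angular_step_keep, :] = True
    elif plan.mode in ("cycloidal", "rotation_only"):
        shift = 0 if plan.mode == "rotation_only" else plan.shift_per_angle
        k = np.arange(n_angles)[:, None]
        mask = (j[None, :] - plan.initial_offset - k * shift) % p < w
    else:  # pragma: no cover - guarded by AcquisitionPlan
        raise ValueError(plan.mode)

    mask[train, :] = True
    return SamplingPattern(mask=mask, plan=plan, training_angles=train)


def apply_pattern(full: Sinogram, pattern: SamplingPattern) -> Sinogram:
    """Keep acquired entries, mark the rest with the NaN missing marker."""
    if full.values.shape != pattern.mask.shape:
        raise ValueError("sinogram and mask shape mismatch")
    vals = np.where(pattern.mask, full.values, np.nan)
    return full.copy_with(vals)


def extract_partial(full: Sinogram, training_angles: list[int]) -> PartialSinogram:
    """Arrange the fully sampled training projections into a partial sinogram."""
    n_angles = full.values.shape[0]
    if any(not (0 <= a < n_angles) for a in training_angles):
        raise ValueError("training angle index out of range")
    defined = np.zeros_like(full.values, dtype=bool)
    defined[list(training_angles), :] = True
    values = np.where(defined, full.values, np.nan)
    return PartialSinogram(values=values, defined=defined)


def dose_fraction(plan: AcquisitionPlan, n_angles: int) -> float:
    """Exposure-weighted dose as a percentage of a complete dithered scan.

    The reference scan acquires ``n_angles * (p / w)`` frames at unit
    exposure.  One cycloidal frame per angle gives ``w / p`` of that;
    interleaved training ditherings count as wholly additional full
    ditherings of their angle (``n_train * p / w`` extra frames).
    """
    p, w = plan.period, plan.aperture
    frames_full = n_angles * (p / w)
    if plan.mode == "dithered":
        base = frames_full
    elif plan.mode == "low_exposure":
        base = frames_full * plan.exposure_fraction
    elif plan.mode == "angular_subsampled":
        n_kept = len(range(0, n_angles, plan.angular_step_keep))
        base = n_kept * (p / w)
    elif plan.mode in ("cycloidal", "rotation_only"):
        base = float(n_angles)
    else:  # pragma: no cover
        raise ValueError(plan.mode)
    training = plan.n_train * (p / w)
    return 100.0 * (base + training) / frames_full
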