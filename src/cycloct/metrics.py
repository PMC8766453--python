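"""Image-quality metrics: PSNR, Dice on thresholded segmentations, MS-SSIM.

Conventions: PSNR and MS-SSIM treat their second argument as the reference;
the PSNR peak and the MS-SSIM data range default to the maximum of the
reference.  Dice is symmetric.  The default segmentation threshold for the
two-material foam is mu / 2, with Otsu and a Dice-maximizing sweep as
alternatives.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu

#: canonical per-scale weights of 5-scale MS-SSIM
MSSSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


@dataclass
class MetricReport:
    """One comparison row: method label, dose and the three image metrics."""

    method: str
    dose_percent: float
    psnr_db: float
    dice: float
    ms_ssim: float
    parameters: str = ""

    def as_row(self) -> dict:
        return asdict(self)


def write_report_csv(path: str, reports: list[MetricReport]) -> None:
    with open(path, "w", newline="") as f:
        w = csv.DictWriter(
            f, fieldnames=["method", "dose_percent", "psnr_db", "dice", "ms_ssim",
                           "parameters"]
        )
        w.writeheader()
        for r in reports:
            w.writerow(r.as_row())


def psnr(image: np.ndarray, reference: np.ndarray, peak: float | None = None) -> float:
    """10 log10(peak^2 / MSE); peak defaults to max(reference)."""
    image = np.asarray(image, float)
    reference = np.asarray(reference, float)
    if image.shape != reference.shape:
        raise ValueError("shape mismatch")
    mse = float(np.mean((image - reference) ** 2))
    if peak is None:
        peak = float(reference.max())
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(peak * peak / mse)


def threshold_segment(
    image: np.ndarray, method: str = "otsu", threshold: float | None = None,
    reference_mask: np.ndarray | None = None, n_sweep: int = 256,
) -> np.ndarray:
    """Binary foreground mask of an image.

    method "otsu": Otsu's threshold; "fixed": the given threshold;
    "sweep": the threshold (out of ``n_sweep`` candidates spanning the
    image range) maximizing Dice against ``reference_mask``.
    """
    image = np.asarray(image, float)
    if not np.all(np.isfinite(image)):
        raise ValueError("non-finite image")
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed thresholding needs a threshold")
        return image > threshold
    if method == "otsu":
        return image > threshold_otsu(image)
    if method == "sweep":
        if reference_mask is None:
            raise ValueError("sweep thresholding needs a reference mask")
        lo, hi = float(image.min()), float(image.max())
        best_t, best_d = lo, -1.0
        for t in np.linspace(lo, hi, n_sweep, endpoint=False):
            d = dice(image > t, reference_mask)
            if d > best_d:
                best_d, best_t = d, t
        return image > best_t
    raise ValueError(f"unknown thresholding method {method!r}")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity 2|a&b| / (|a| + |b|); 1.0 when both masks are empty."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def _ssim_maps(x: np.ndarray, y: np.ndarray, data_range: float,
               sigma: float = 1.5, truncate: float = 3.5,
               k1: float = 0.01, k2: float = 0.03):
    """Cropped luminance*structure (full SSIM) and contrast-structure maps."""
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    filt = lambda im: gaussian_filter(im, sigma, mode="nearest", truncate=truncate)
    ux, uy = filt(x), filt(y)
    uxx, uyy, uxy = filt(x * x), filt(y * y), filt(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    cxy = uxy - ux * uy
    cs = (2 * cxy + c2) / (vx + vy + c2)
    ssim = ((2 * ux * uy + c1) / (ux ** 2 + uy ** 2 + c1)) * cs
    pad = int(truncate * sigma + 0.5)  # ignore filter-boundary artefacts
    sl = (slice(pad, -pad), slice(pad, -pad))
    return ssim[sl], cs[sl]


def ms_ssim(image: np.ndarray, reference: np.ndarray, scales: int = 5,
            data_range: float | None = None) -> float:
    """Multiscale structural similarity (5 dyadic scales by default).

    Canonical per-scale weights, 11x11 Gaussian window (sigma 1.5); the
    data range defaults to the reference peak.  If the images are too small
    for the requested number of scales, the count is reduced with a warning
    and the weights renormalized.
    """
    x = np.asarray(image, float)
    y = np.asarray(reference, float)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    if data_range is None:
        data_range = float(y.max() - min(y.min(), 0.0)) or 1.0

    win = 11
    usable = scales
    while usable > 1 and min(x.shape) // 2 ** (usable - 1) < win:
        usable -= 1
    if usable < scales:
        warnings.warn(
            f"image too small for {scales} MS-SSIM scales; using {usable}",
            stacklevel=2,
        )
    weights = np.array(MSSSIM_WEIGHTS[:usable])
    weights = weights / weights.sum()

    vals = []
    for s in range(usable):
        ssim_map, cs_map = _ssim_maps(x, y, data_range)
        if s == usable - 1:
            vals.append(max(float(ssim_map.mean()), 0.0))
        else:
            vals.append(max(float(cs_map.mean()), 0.0))
            # low-pass and dyadic downsample (2x2 average pooling)
            h, w = (x.shape[0] // 2) * 2, (x.shape[1] // 2) * 2
            x = x[:h, :w].reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))
            y = y[:h, :w].reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))
    return float(np.prod(np.array(vals) ** weights))
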