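"""Baseline sinogram completion by bicubic spline interpolation.

Missing sinogram entries are filled by piecewise-cubic C1 interpolation
(Clough-Tocher) over the scattered acquired points in (angle-index,
column-index) coordinates.  The interpolant is exact at the acquired points
and reproduces linear functions exactly.  Outside the convex hull of the
acquired points — at most a thin border near the first/last angles and the
detector edges — missing entries take the value of the nearest acquired
point.

Fully sampled training rows participate as ordinary data points, so the
interpolation is anchored by exact rows at the training angles.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CloughTocher2DInterpolator, NearestNDInterpolator

from .forward_model import Sinogram
from .sampling import SamplingPattern


def bicubic_interpolate(incomplete: Sinogram, pattern: SamplingPattern) -> Sinogram:
    """Complete an incomplete sinogram from its acquired entries.

    Parameters
    ----------
    incomplete : Sinogram
        Values at acquired entries; anything outside the mask is ignored.
    pattern : SamplingPattern
        Boolean mask of acquired entries (source of truth).

    Returns
    -------
    Sinogram
        Complete sinogram equal to the input at acquired entries.
    """
    mask = pattern.mask
    vals = incomplete.values
    if vals.shape != mask.shape:
        raise ValueError("sinogram and mask shape mismatch")
    if mask.all():
        return incomplete.copy_with(vals)
    if not np.isfinite(vals[mask]).all():
        raise ValueError("non-finite values at acquired entries")

    ki, ji = np.nonzero(mask)
    if ki.size < 16 or np.unique(ki).size < 4 or np.unique(ji).size < 4:
        raise ValueError("insufficient sampling support for bicubic completion")

    pts = np.column_stack([ki, ji]).astype(np.float64)
    data = vals[mask]
    kq, jq = np.nonzero(~mask)
    query = np.column_stack([kq, jq]).astype(np.float64)

    filled = CloughTocher2DInterpolator(pts, data)(query)
    hole = ~np.isfinite(filled)  # outside the convex hull
    if hole.any():
        filled[hole] = NearestNDInterpolator(pts, data)(query[hole])

    out = vals.copy()
    out[kq, jq] = filled
    out[mask] = vals[mask]  # exact at data points by construction
    return incomplete.copy_with(out)
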