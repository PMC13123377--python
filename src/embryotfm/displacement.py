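"""Gel displacement estimation from loaded vs relaxed bead images.

Displacement fields are computed PIV-style: the loaded and relaxed
(reference) images are divided into overlapping interrogation windows,
each window pair is matched by normalized cross-correlation, and the
correlation peak is located with subpixel precision by a 2-D Gaussian fit
(a second deformation pass removes gradient bias).  The sign convention
is loaded-relative-to-relaxed: a bead pulled toward the embryo yields a
displacement vector pointing toward the embryo, so tractions
reconstructed from the field are those the embryo exerts.

Windows devoid of beads (near-zero variance) or with a weak correlation
peak are masked invalid.  Spurious vectors are removed by a local
median/MAD test and fields can be resampled to any uniform grid for the
Fourier inversion.
"""
from __future__ import annotations

import logging
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.interpolate import (
    LinearNDInterpolator,
    NearestNDInterpolator,
    RectBivariateSpline,
)
from skimage.feature import match_template

from .fields import DisplacementField

logger = logging.getLogger(__name__)

__all__ = [
    "compute_displacement_field",
    "filter_outliers",
    "interpolate_to_grid",
]


def _subpixel_offset(c: np.ndarray, peak: Tuple[int, int]) -> Tuple[float, float]:
    """Subpixel peak offset (dy, dx) from the correlation surface.

    Fits a 2-D Gaussian (quadratic in log space) to the 3×3 neighbourhood
    of the peak, which captures the cross term the separable 3-point fit
    ignores; falls back to the separable Gaussian/parabolic fit when the
    neighbourhood is unusable (non-positive values or a saddle).
    """
    py, px = peak
    ny, nx = c.shape
    if 0 < py < ny - 1 and 0 < px < nx - 1:
        n = c[py - 1: py + 2, px - 1: px + 2]
        if n.min() > 0 and np.argmax(n) == 4:
            ys, xs = np.mgrid[-1:2, -1:2]
            A = np.column_stack(
                [np.ones(9), xs.ravel(), ys.ravel(), xs.ravel() ** 2,
                 xs.ravel() * ys.ravel(), ys.ravel() ** 2]
            )
            coef, *_ = np.linalg.lstsq(A, np.log(n.ravel()), rcond=None)
            _, a1, a2, a3, a4, a5 = coef
            det = 4 * a3 * a5 - a4 ** 2
            if det > 0 and a3 < 0 and a5 < 0:
                sx = (-2 * a5 * a1 + a4 * a2) / det
                sy = (-2 * a3 * a2 + a4 * a1) / det
                if abs(sx) <= 1 and abs(sy) <= 1:
                    return sy, sx
    return _subpixel_separable(c, peak)


def _subpixel_separable(
    c: np.ndarray, peak: Tuple[int, int]
) -> Tuple[float, float]:
    """Separable 3-point Gaussian peak interpolation along each axis."""
    py, px = peak
    ny, nx = c.shape
    out = []
    for axis, p, n in (("y", py, ny), ("x", px, nx)):
        if p in (0, n - 1):
            out.append(0.0)
            continue
        if axis == "y":
            cm, c0, cp = c[p - 1, px], c[p, px], c[p + 1, px]
        else:
            cm, c0, cp = c[py, p - 1], c[py, p], c[py, p + 1]
        if min(cm, c0, cp) <= 0 or c0 < max(cm, cp):
            # fall back to parabolic fit when logs are unusable
            denom = cm - 2 * c0 + cp
            out.append(0.0 if denom == 0 else 0.5 * (cm - cp) / denom)
            continue
        lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
        denom = 2 * lm - 4 * l0 + 2 * lp
        out.append(0.0 if denom == 0 else (lm - lp) / denom)
    return out[0], out[1]


def _window_correlate(
    ref: np.ndarray, load: np.ndarray, margin: Optional[int] = None
) -> Tuple[float, float, float]:
    """Normalized cross-correlation of one window pair; (dx, dy, quality).

    The interior of the reference window (inset by ``margin`` px, default a
    quarter of the window) is used as template and matched across the full
    loaded window, so every candidate shift up to ±margin is evaluated on a
    complete overlap — this avoids the toward-zero bias of circular
    correlation when beads cross window edges.  Quality is the NCC peak
    value (1 for a perfect match).
    """
    if margin is None:
        margin = max(ref.shape[0] // 4, 3)
    template = ref[margin:-margin, margin:-margin]
    if float(template.std()) == 0.0 or float(load.std()) == 0.0:
        return 0.0, 0.0, 0.0
    c = match_template(load, template)
    peak = np.unravel_index(np.argmax(c), c.shape)
    if c[peak] > 1.0 - 1e-9:
        # exact match (identical images): the integer peak is the answer,
        # and asymmetric NCC neighbours would fake a subpixel offset
        return float(peak[1] - margin), float(peak[0] - margin), float(c[peak])
    sy, sx = _subpixel_offset(c, peak)
    dy = peak[0] - margin + sy
    dx = peak[1] - margin + sx
    return dx, dy, float(c[peak])


def _piv_pass(
    loaded: np.ndarray,
    reference: np.ndarray,
    window_size: int,
    step: int,
    pixel_size: float,
    min_quality: float,
) -> DisplacementField:
    h, w = loaded.shape
    ys = np.arange(0, h - window_size + 1, step)
    xs = np.arange(0, w - window_size + 1, step)
    if ys.size < 3 or xs.size < 3:
        raise ValueError("images too small for the requested window grid")
    u = np.zeros((ys.size, xs.size))
    v = np.zeros_like(u)
    quality = np.zeros_like(u)
    mask = np.zeros(u.shape, dtype=bool)
    for iy, y0 in enumerate(ys):
        for ix, x0 in enumerate(xs):
            rwin = reference[y0: y0 + window_size, x0: x0 + window_size]
            lwin = loaded[y0: y0 + window_size, x0: x0 + window_size]
            dx, dy, q = _window_correlate(rwin, lwin)
            u[iy, ix] = dx * pixel_size
            v[iy, ix] = dy * pixel_size
            quality[iy, ix] = q
            mask[iy, ix] = q >= min_quality
    n_bad = int((~mask).sum())
    if n_bad:
        logger.info("%d of %d windows masked invalid", n_bad, mask.size)
    centers_x = (xs + window_size / 2.0) * pixel_size
    centers_y = (ys + window_size / 2.0) * pixel_size
    return DisplacementField(centers_x, centers_y, u, v, mask, quality)


def compute_displacement_field(
    loaded: np.ndarray,
    reference: np.ndarray,
    window_size: int = 32,
    overlap: float = 0.75,
    pixel_size: float = 0.5,
    min_quality: float = 0.05,
    passes: int = 2,
) -> DisplacementField:
    """PIV displacement field between a loaded and a relaxed bead image.

    Parameters
    ----------
    loaded, reference : 2-D arrays
        Drift-corrected bead image with the embryo attached, and the
        relaxed image after embryo removal.  Must share a shape.
    window_size : int
        Interrogation window edge in px (≥ 16).
    overlap : float
        Fractional window overlap in [0, 1).
    pixel_size : float
        μm per pixel; output coordinates and displacements are in μm.
    min_quality : float
        Windows with normalized peak correlation below this are masked.
    passes : int
        Number of correlation passes.  Passes after the first warp the
        loaded image by the current field estimate (window deformation)
        and measure the residual shift, which removes most of the
        gradient-induced bias of single-pass window correlation.
    """
    loaded = np.asarray(loaded, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if loaded.shape != reference.shape:
        raise ValueError("loaded and reference images must share a shape")
    if window_size < 16:
        raise ValueError("window_size must be at least 16 px")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    if passes < 1:
        raise ValueError("passes must be >= 1")

    step = max(int(round(window_size * (1.0 - overlap))), 1)
    field = _piv_pass(loaded, reference, window_size, step, pixel_size,
                      min_quality)
    for _ in range(passes - 1):
        field, _ = filter_outliers(field)
        # smooth dense per-pixel displacement (px) from the node field;
        # spline continuation matters in high-gradient regions
        h, w = loaded.shape
        su = RectBivariateSpline(field.y / pixel_size, field.x / pixel_size,
                                 field.u / pixel_size)
        sv = RectBivariateSpline(field.y / pixel_size, field.x / pixel_size,
                                 field.v / pixel_size)
        u_px = su(np.arange(h), np.arange(w))
        v_px = sv(np.arange(h), np.arange(w))
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        warped = ndimage.map_coordinates(
            loaded, [yy + v_px, xx + u_px], order=1, mode="nearest"
        )
        resid = _piv_pass(warped, reference, window_size, step, pixel_size,
                          min_quality)
        field = DisplacementField(
            field.x, field.y,
            field.u + resid.u, field.v + resid.v,
            field.mask & resid.mask, resid.quality,
        )
    return field


def filter_outliers(
    field: DisplacementField,
    median_window: int = 3,
    threshold: float = 3.0,
    noise_floor: float = 0.02,
) -> Tuple[DisplacementField, int]:
    """Replace spurious vectors by the local median (universal outlier test).

    A node is an outlier when its residual from the local median exceeds
    ``threshold`` × (local MAD + ``noise_floor``).  The noise floor (μm)
    represents the irreducible subpixel measurement noise, so smooth but
    curved fields — where residual and MAD are both tiny — are not
    mistaken for outliers.  Returns the filtered field and the replacement
    count.
    """
    if field.mask is not None and not field.mask.any():
        raise ValueError("all nodes invalid")
    out = field.copy()
    eps = max(noise_floor, 1e-3 * float(np.max(field.magnitude)))
    n_replaced = 0
    for comp in ("u", "v"):
        a = getattr(out, comp)
        med = ndimage.median_filter(a, size=median_window, mode="nearest")
        resid = np.abs(a - med)
        mad = ndimage.median_filter(resid, size=median_window, mode="nearest")
        bad = resid > threshold * (mad + eps)
        a[bad] = med[bad]
        n_replaced += int(bad.sum())
    if n_replaced:
        logger.info("replaced %d outlier components", n_replaced)
    return out, n_replaced


def interpolate_to_grid(
    field: DisplacementField,
    spacing: float,
) -> DisplacementField:
    """Resample valid nodes onto a uniform grid of the given spacing (μm).

    Linear interpolation (exact on constant and linear-ramp fields) inside
    the convex hull of valid nodes; nodes outside the hull are filled by
    nearest-neighbour values and flagged invalid in the mask.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    valid = field.mask if field.mask is not None else np.ones(field.u.shape, bool)
    if valid.sum() < 4:
        raise ValueError("need at least 4 valid nodes")
    X, Y = np.meshgrid(field.x, field.y)
    pts = np.column_stack([X[valid], Y[valid]])
    new_x = np.arange(field.x[0], field.x[-1] + 0.5 * spacing, spacing)
    new_y = np.arange(field.y[0], field.y[-1] + 0.5 * spacing, spacing)
    NX, NY = np.meshgrid(new_x, new_y)
    tgt = np.column_stack([NX.ravel(), NY.ravel()])

    comps = []
    hull_ok = None
    for comp in ("u", "v"):
        vals = getattr(field, comp)[valid]
        lin = LinearNDInterpolator(pts, vals)
        near = NearestNDInterpolator(pts, vals)
        z = lin(tgt)
        outside = np.isnan(z)
        z[outside] = near(tgt[outside])
        comps.append(z.reshape(NY.shape))
        hull_ok = ~outside.reshape(NY.shape)
    return DisplacementField(new_x, new_y, comps[0], comps[1], hull_ok)
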