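"""Shape, interface and motility quantification for embryo image analysis.

Covers the morphological readouts used to compare embryos across substrate
stiffness: projected circularity and area, the epiblast (EPI) / polar
trophectoderm (pTE) interface geometry, the core-structure diameter rule
(equivalent diameter strictly greater than 80 μm), migration statistics
(speed, directionality ratio, MSD and its power-law exponent), and the
adhesion-onset inflection of area–circularity time courses.

Conventions chosen here because the underlying quantities admit several
definitions (all flagged in docs/methods.md):

* interface curvature is reported as the angle (degrees) subtended by the
  interface polyline on its least-squares circle;
* "relative interface" is the interface chord divided by the EPI width
  (the EPI extent perpendicular to the EPI→pTE axis), so a full-width
  interface gives 1;
* MSD is time-averaged over all start points, and the power-law exponent
  is fitted on lags up to a quarter of the track span.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats
from skimage import measure

from .series import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "ShapeMetrics",
    "InterfaceMetrics",
    "MigrationStats",
    "InflectionResult",
    "shape_metrics",
    "interface_metrics",
    "core_structure_test",
    "migration_stats",
    "adhesion_inflection",
]


@dataclass
class ShapeMetrics:
    area: float                 # μm²
    perimeter: float            # μm
    circularity: float          # 4πA/P²
    equivalent_diameter: float  # μm


@dataclass
class InterfaceMetrics:
    epi_area: float             # μm²
    pte_area: float             # μm²
    interface_length: float     # μm, polyline arc
    interface_diameter: float   # μm, endpoint chord
    curvature: float            # degrees subtended on the fitted circle
    relative_interface: float   # chord / EPI width
    epi_height: float           # μm, extent along the EPI→pTE axis
    epi_width: float            # μm, extent perpendicular to the axis
    pte_height: float           # μm


@dataclass
class MigrationStats:
    speed: float                # μm/min
    directionality_ratio: float
    msd_lags: np.ndarray        # min
    msd: np.ndarray             # μm²
    msd_exponent: float
    stationary: bool = False    # directionality undefined when True


@dataclass
class InflectionResult:
    breakpoint_time: Optional[float]
    flagged: bool
    reason: str = ""
    ssr: float = np.nan


# ---------------------------------------------------------------------------
# projected shape
# ---------------------------------------------------------------------------

def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels = measure.label(mask)
    if labels.max() == 0:
        raise ValueError("empty mask")
    if labels.max() > 1:
        logger.info("mask has %d components; taking the largest", labels.max())
        sizes = np.bincount(labels.ravel())[1:]
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask.astype(bool)


def _contour_perimeter(mask: np.ndarray, smooth: int = 5) -> float:
    """Boundary length from the marching-squares contour polyline.

    The raw contour staircases on curved boundaries (overestimating a
    disk's perimeter by ~5%), so the polyline is lightly smoothed with a
    circular moving average before measuring; straight edges are barely
    affected.
    """
    from scipy.ndimage import uniform_filter1d

    padded = np.pad(mask, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return 0.0
    c = max(contours, key=len)
    if smooth > 1 and c.shape[0] > smooth:
        c = np.column_stack(
            [uniform_filter1d(c[:, 0], smooth, mode="wrap"),
             uniform_filter1d(c[:, 1], smooth, mode="wrap")]
        )
    closed = np.vstack([c, c[:1]])
    return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))


def shape_metrics(mask: np.ndarray, pixel_size: float = 1.0) -> ShapeMetrics:
    """Projected area, perimeter and circularity of a binary embryo mask.

    Perimeter is measured on the lightly smoothed marching-squares
    contour, which is within ~1% on digital disks and ~2% on rectangles.
    Circularity 4πA/P² is 1 for a circle and π/4 for a square.
    """
    mask = _largest_component(np.asarray(mask, dtype=bool))
    area_px = float(mask.sum())
    perim_px = _contour_perimeter(mask)
    if perim_px == 0:
        raise ValueError("mask has no measurable boundary")
    area = area_px * pixel_size ** 2
    perimeter = perim_px * pixel_size
    circ = 4.0 * np.pi * area / perimeter ** 2
    eq_diam = 2.0 * np.sqrt(area / np.pi)
    return ShapeMetrics(area, perimeter, circ, eq_diam)


def core_structure_test(
    mask: np.ndarray, pixel_size: float = 1.0
) -> Tuple[bool, float]:
    """Core-structure rule: equivalent diameter strictly greater than 80 μm."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    area = float(mask.sum()) * pixel_size ** 2
    eq_diam = 2.0 * np.sqrt(area / np.pi)
    return eq_diam > 80.0, eq_diam


# ---------------------------------------------------------------------------
# EPI / pTE interface
# ---------------------------------------------------------------------------

def _order_polyline(points: np.ndarray) -> np.ndarray:
    """Order scattered boundary pixels into a path by nearest-neighbour walk.

    Starts from the point farthest from the centroid-side midpoint (an
    endpoint for open arcs) and greedily chains nearest unvisited points.
    """
    n = points.shape[0]
    if n <= 2:
        return points
    # endpoint heuristic: farthest point from the set centroid
    centroid = points.mean(axis=0)
    start = int(np.argmax(np.linalg.norm(points - centroid, axis=1)))
    visited = np.zeros(n, dtype=bool)
    order = [start]
    visited[start] = True
    for _ in range(n - 1):
        cur = points[order[-1]]
        d = np.linalg.norm(points - cur, axis=1)
        d[visited] = np.inf
        nxt = int(np.argmin(d))
        order.append(nxt)
        visited[nxt] = True
    return points[order]


def _fit_circle(points: np.ndarray) -> Tuple[float, float, float]:
    """Algebraic (Kåsa) least-squares circle fit; returns (cx, cy, radius)."""
    x, y = points[:, 0], points[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x ** 2 + y ** 2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r = np.sqrt(max(c + cx ** 2 + cy ** 2, 0.0))
    return float(cx), float(cy), float(r)


def _angular_extent_deg(points: np.ndarray, cx: float, cy: float) -> float:
    """Angle (degrees) subtended by points around (cx, cy): 360° − largest gap."""
    ang = np.sort(np.arctan2(points[:, 1] - cy, points[:, 0] - cx))
    gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
    return float(np.degrees(2 * np.pi - gaps.max()))


def interface_metrics(
    epi_mask: np.ndarray,
    pte_mask: np.ndarray,
    pixel_size: float = 1.0,
) -> InterfaceMetrics:
    """Geometry of the shared EPI/pTE boundary.

    The interface polyline is the chain of EPI boundary pixels that touch
    (8-connectivity) the pTE mask.  Arc length is the polyline length,
    chord the endpoint distance, and curvature the subtended angle of the
    least-squares circle through the polyline (0° for a straight
    interface).
    """
    epi = np.asarray(epi_mask, dtype=bool)
    pte = np.asarray(pte_mask, dtype=bool)
    if epi.shape != pte.shape:
        raise ValueError("masks must share a shape")
    if np.any(epi & pte):
        raise ValueError("EPI and pTE masks must not overlap")
    # EPI pixels 8-adjacent to pTE
    from scipy.ndimage import binary_dilation

    touch = epi & binary_dilation(pte, structure=np.ones((3, 3), bool))
    if not touch.any():
        raise ValueError("no shared boundary between EPI and pTE masks")
    ys, xs = np.nonzero(touch)
    pts = np.column_stack([xs, ys]).astype(float) * pixel_size
    path = _order_polyline(pts)
    seglen = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arc = float(seglen.sum())
    chord = float(np.linalg.norm(path[-1] - path[0]))
    arc = max(arc, chord)  # discrete polylines cannot subtend less than the chord

    # curvature: straight-line degeneracy guard, then circle fit
    if path.shape[0] < 3:
        curvature = 0.0
    else:
        # residual of the best straight line through the points
        centered = path - path.mean(axis=0)
        _, s, _ = np.linalg.svd(centered, full_matrices=False)
        line_resid = s[-1] / np.sqrt(path.shape[0])
        if line_resid < 0.35 * pixel_size:  # straight within rasterization
            curvature = 0.0
        else:
            cx, cy, r = _fit_circle(path)
            if r > 100.0 * max(chord, pixel_size):
                curvature = 0.0
            else:
                curvature = _angular_extent_deg(path, cx, cy)

    # geometry along the EPI -> pTE axis
    epi_pts = np.argwhere(epi)[:, ::-1].astype(float) * pixel_size
    pte_pts = np.argwhere(pte)[:, ::-1].astype(float) * pixel_size
    axis = pte_pts.mean(axis=0) - epi_pts.mean(axis=0)
    norm = np.linalg.norm(axis)
    axis = axis / norm if norm > 0 else np.array([0.0, 1.0])
    perp = np.array([-axis[1], axis[0]])
    epi_height = float(np.ptp(epi_pts @ axis))
    epi_width = float(np.ptp(epi_pts @ perp))
    pte_height = float(np.ptp(pte_pts @ axis))
    rel = chord / epi_width if epi_width > 0 else np.nan

    return InterfaceMetrics(
        epi_area=float(epi.sum()) * pixel_size ** 2,
        pte_area=float(pte.sum()) * pixel_size ** 2,
        interface_length=arc,
        interface_diameter=chord,
        curvature=curvature,
        relative_interface=rel,
        epi_height=epi_height,
        epi_width=epi_width,
        pte_height=pte_height,
    )


# ---------------------------------------------------------------------------
# migration
# ---------------------------------------------------------------------------

def migration_stats(trajectory: Trajectory, max_lag_fraction: float = 0.25
                    ) -> MigrationStats:
    """Speed, directionality ratio and MSD statistics of a trajectory.

    speed = path length / elapsed time; directionality ratio = net
    displacement / path length (undefined for a stationary track, flagged);
    MSD(τ) is time-averaged over all pairs at lag τ and its power-law
    exponent comes from a log–log regression over lags up to
    ``max_lag_fraction`` of the track span.
    """
    if len(trajectory) < 3:
        raise ValueError("need at least 3 points")
    t = trajectory.times
    pos = trajectory.positions
    elapsed = t[-1] - t[0]
    path = trajectory.path_length
    speed = path / elapsed
    if path == 0:
        logger.info("zero path length: directionality ratio undefined")
        n = len(trajectory)
        lags = t[1: max(2, int(np.floor(n * max_lag_fraction)) + 1)] - t[0]
        return MigrationStats(0.0, np.nan, lags, np.zeros(lags.size), np.nan,
                              stationary=True)
    ratio = trajectory.net_displacement / path

    n = len(trajectory)
    max_lag = max(2, int(np.floor((n - 1) * max_lag_fraction)))
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(lags.size)
    for i, lag in enumerate(lags):
        d = pos[lag:] - pos[:-lag]
        msd[i] = float(np.mean(np.sum(d * d, axis=1)))
    lag_times = lags * float(np.median(np.diff(t)))
    ok = msd > 0
    if ok.sum() >= 2:
        fit = stats.linregress(np.log(lag_times[ok]), np.log(msd[ok]))
        exponent = float(fit.slope)
    else:
        exponent = np.nan
    return MigrationStats(float(speed), float(ratio), lag_times, msd, exponent)


# ---------------------------------------------------------------------------
# adhesion-onset inflection
# ---------------------------------------------------------------------------

def adhesion_inflection(
    times: np.ndarray,
    area: np.ndarray,
    circularity: np.ndarray,
) -> InflectionResult:
    """Breakpoint of the area–circularity trajectory parameterized by time.

    Both series are z-scored and jointly fitted with a continuous
    two-segment piecewise-linear model sharing one breakpoint; the
    breakpoint time minimizing the total squared residual is returned.
    When a single line already explains the data (collinear trajectory)
    the breakpoint is undefined and flagged.
    """
    t = np.asarray(times, dtype=float)
    series = []
    for arr in (area, circularity):
        a = np.asarray(arr, dtype=float)
        if a.shape != t.shape:
            raise ValueError("series must share the time base")
        sd = a.std()
        series.append((a - a.mean()) / sd if sd > 0 else a - a.mean())
    n = t.size
    if n < 8:
        raise ValueError("need at least 8 samples")

    def ssr_line(y: np.ndarray) -> float:
        A = np.column_stack([np.ones(n), t])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        r = y - A @ coef
        return float(r @ r)

    def ssr_break(y: np.ndarray, tb: float) -> float:
        A = np.column_stack([np.ones(n), t, np.maximum(t - tb, 0.0)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        r = y - A @ coef
        return float(r @ r)

    ssr_one = sum(ssr_line(y) for y in series)
    candidates = t[2:-2]
    if candidates.size == 0:
        raise ValueError("too few interior samples for a two-segment fit")
    ssrs = np.array([sum(ssr_break(y, tb) for y in series) for tb in candidates])
    best = int(np.argmin(ssrs))
    improvement = 1.0 - ssrs[best] / ssr_one if ssr_one > 0 else 0.0
    if ssr_one < 1e-12 * n or improvement < 0.01:
        return InflectionResult(None, True, "segments collinear", ssrs[best])
    return InflectionResult(float(candidates[best]), False, "", float(ssrs[best]))
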