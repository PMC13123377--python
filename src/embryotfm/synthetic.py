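"""Forward simulation of every input the analysis pipeline consumes.

Each generator produces data with known ground truth so downstream stages
can be validated by parameter recovery:

* contractile, force-balanced traction patterns (an annular ring of
  inward-pointing tractions mimicking the peripheral pulling of an adherent
  embryo) and the surface displacements they produce on a soft gel;
* fluorescent-bead images before (relaxed) and after (loaded) the gel is
  deformed, with rigid stage drift and optional counting noise;
* max-traction time courses that ramp during adhesion and then fluctuate
  with quasi-periodic peaks (~10-min recurrence);
* persistent-random-walk embryo trajectories sampled at fixed intervals;
* Hertzian force–indentation curves for a spherical nanoindenter tip;
* two-channel cell/nucleus images with prescribed region intensities for
  nuclear/cytoplasmic ratio checks.

All randomness flows through an explicit seed; a fixed seed gives
bit-identical output.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .elastic import crop_field, kernel_components, pad_field, wavevectors
from .fields import DisplacementField, GelProperties, TractionField
from .indentation import IndentationCurve, hertz_force
from .series import TimeSeries, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "GroundTruthScene",
    "PeakTrainSpec",
    "make_contractile_traction",
    "scene_for_stiffness",
    "forward_displacement",
    "make_scene",
    "render_bead_images",
    "gen_peak_series",
    "gen_trajectory",
    "gen_indentation_curve",
    "gen_yap_cell_image",
]


# ---------------------------------------------------------------------------
# traction ground truth and forward elasticity
# ---------------------------------------------------------------------------

def make_contractile_traction(
    shape: Tuple[int, int] = (96, 96),
    spacing: float = 2.0,
    center: Optional[Tuple[float, float]] = None,
    r_inner: float = 30.0,
    r_outer: float = 55.0,
    peak: float = 100.0,
) -> TractionField:
    """Annulus of inward-pointing radial tractions, self-balanced.

    Parameters
    ----------
    shape : (ny, nx)
        Grid shape; each axis needs more than 2 nodes.
    spacing : float
        Grid spacing, μm.
    center : (cx, cy) or None
        Annulus centre in μm; defaults to the grid centre.
    r_inner, r_outer : float
        Annulus radii, μm (``r_inner < r_outer``).
    peak : float
        Peak traction magnitude, Pa.  A cosine bump profile across the
        annulus keeps the field smooth (band-limited), which matters for
        Fourier-based inversion.

    The returned field is exactly balanced: after construction any residual
    discretization imbalance is removed by subtracting the (tiny) mean
    traction from each component.
    """
    ny, nx = shape
    if ny <= 2 or nx <= 2:
        raise ValueError("degenerate grid: need more than 2 nodes per axis")
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    if not r_inner < r_outer:
        raise ValueError("r_inner must be less than r_outer")
    x = np.arange(nx) * spacing
    y = np.arange(ny) * spacing
    if center is None:
        center = (x.mean(), y.mean())
    cx, cy = center
    X, Y = np.meshgrid(x, y)
    dx = X - cx
    dy = Y - cy
    r = np.hypot(dx, dy)
    mid = 0.5 * (r_inner + r_outer)
    half = 0.5 * (r_outer - r_inner)
    profile = np.where(
        (r >= r_inner) & (r <= r_outer),
        0.5 * (1.0 + np.cos(np.pi * (r - mid) / half)),
        0.0,
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(r > 0, -dx / r, 0.0)
        uy = np.where(r > 0, -dy / r, 0.0)
    tx = peak * profile * ux
    ty = peak * profile * uy
    # enforce exact balance against rasterization asymmetry
    tx -= tx.mean()
    ty -= ty.mean()
    return TractionField(x, y, tx, ty)


def forward_displacement(
    traction: TractionField,
    gel: GelProperties,
    pad_factor: int = 1,
) -> DisplacementField:
    """Surface displacement produced by a traction field on a gel.

    Evaluates ũ = G̃ T̃ per Fourier mode with the Boussinesq half-space
    kernel and transforms back.  Displacement is linear in T and scales as
    1/E.

    The default ``pad_factor=1`` treats the grid as one period of the
    spectral model — the same convention the inverse uses — so ground
    truth and reconstruction share a single self-consistent operator.
    ``pad_factor>1`` zero-pads the (compactly supported) tractions before
    the FFT, approximating the aperiodic convolution of an isolated
    embryo; the result is cropped back to the input grid.
    """
    ny, nx = traction.tx.shape
    tx = pad_field(traction.tx, pad_factor, taper=False)
    ty = pad_field(traction.ty, pad_factor, taper=False)
    KX, KY = wavevectors(*tx.shape, spacing=traction.spacing)
    gxx, gxy, gyy = kernel_components(KX, KY, gel)
    ftx = np.fft.fft2(tx)
    fty = np.fft.fft2(ty)
    fu = gxx * ftx + gxy * fty
    fv = gxy * ftx + gyy * fty
    u = np.real(np.fft.ifft2(fu))
    v = np.real(np.fft.ifft2(fv))
    return DisplacementField(
        traction.x.copy(), traction.y.copy(),
        crop_field(u, (ny, nx)), crop_field(v, (ny, nx)),
    )


def scene_for_stiffness(
    youngs_modulus: float,
    seed: int = 0,
    total_force_nn: float = 300.0,
    reference_modulus: float = 1000.0,
    spread_exponent: float = 0.15,
    **scene_kwargs,
) -> "GroundTruthScene":
    """Scene with a stiffness-adapted embryo force program.

    Emulates the observed mechanical response of implanting embryos:
    a finite total force output that is redistributed as substrate
    stiffness changes.  Adhesion area grows with stiffness (contact radii
    scale as (E/E_ref)^spread_exponent), so at fixed total force the peak
    traction stress falls as the substrate stiffens.
    """
    s = (youngs_modulus / reference_modulus) ** spread_exponent
    r_inner = 30.0 * s
    r_outer = 55.0 * s
    gel = GelProperties(youngs_modulus=youngs_modulus, poisson_ratio=0.5)
    scene = make_scene(seed=seed, gel=gel, r_inner=r_inner, r_outer=r_outer,
                       peak=100.0, **scene_kwargs)
    t = scene.traction_truth
    integral_nn = float(np.sum(t.magnitude)) * t.node_area * 1e-3
    factor = total_force_nn / integral_nn
    scene.traction_truth = TractionField(
        t.x, t.y, t.tx * factor, t.ty * factor
    )
    return scene


# ---------------------------------------------------------------------------
# bead scene
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthScene:
    """A complete synthetic TFM acquisition with known ground truth.

    ``bead_positions_reference`` are relaxed-state bead centres in μm;
    ``drift_per_frame`` holds one rigid (dx, dy) stage shift in pixels per
    loaded frame.  ``noise`` maps 'amplitude', 'background' (counts) and
    'counting_noise' (bool: apply Poisson statistics).
    """

    traction_truth: TractionField
    gel: GelProperties
    bead_positions_reference: np.ndarray
    drift_per_frame: np.ndarray
    pixel_size: float
    seed: int
    noise: dict = dc_field(default_factory=dict)
    bead_sigma_px: float = 1.5

    def __post_init__(self) -> None:
        self.bead_positions_reference = np.asarray(
            self.bead_positions_reference, dtype=float
        )
        self.drift_per_frame = np.atleast_2d(
            np.asarray(self.drift_per_frame, dtype=float)
        )
        imbalance = self.traction_truth.net_force_imbalance()
        if imbalance > 1e-6:
            raise ValueError(
                f"traction_truth is not force-balanced (imbalance {imbalance:.2e})"
            )

    @property
    def field_of_view(self) -> Tuple[float, float]:
        """(width, height) of the imaged region in μm."""
        return (
            float(self.traction_truth.x[-1] + self.traction_truth.spacing),
            float(self.traction_truth.y[-1] + self.traction_truth.spacing),
        )


def make_scene(
    seed: int = 0,
    gel: Optional[GelProperties] = None,
    shape: Tuple[int, int] = (96, 96),
    spacing: float = 2.0,
    peak: float = 100.0,
    r_inner: float = 30.0,
    r_outer: float = 55.0,
    bead_density: float = 0.06,
    pixel_size: float = 0.5,
    n_frames: int = 1,
    drift_sd_px: float = 1.5,
    amplitude: float = 3000.0,
    background: float = 100.0,
    counting_noise: bool = True,
) -> GroundTruthScene:
    """Assemble a default ground-truth scene.

    ``bead_density`` is beads per μm² of the monolayer plane (default 0.06,
    roughly one bead per 4 μm — a dense, well-distributed single plane of
    fiducial markers).  Stage drift per frame is drawn from a normal with
    ``drift_sd_px`` pixels SD per axis.
    """
    rng = np.random.default_rng(seed)
    if gel is None:
        gel = GelProperties(youngs_modulus=1000.0, poisson_ratio=0.5)
    traction = make_contractile_traction(
        shape=shape, spacing=spacing, peak=peak,
        r_inner=r_inner, r_outer=r_outer,
    )
    width = shape[1] * spacing
    height = shape[0] * spacing
    n_beads = rng.poisson(bead_density * width * height)
    beads = np.column_stack(
        [rng.uniform(0, width, n_beads), rng.uniform(0, height, n_beads)]
    )
    drift = rng.normal(0.0, drift_sd_px, size=(n_frames, 2))
    return GroundTruthScene(
        traction_truth=traction,
        gel=gel,
        bead_positions_reference=beads,
        drift_per_frame=drift,
        pixel_size=pixel_size,
        seed=seed,
        noise={
            "amplitude": amplitude,
            "background": background,
            "counting_noise": counting_noise,
        },
    )


def _render_spots(
    centers_px: np.ndarray,
    shape: Tuple[int, int],
    sigma: float,
    amplitude: float,
) -> np.ndarray:
    """Sum of isotropic Gaussian spots on a pixel canvas."""
    canvas = np.zeros(shape, dtype=float)
    ny, nx = shape
    halfw = int(np.ceil(4 * sigma))
    for cx, cy in centers_px:
        ix, iy = int(round(cx)), int(round(cy))
        x0, x1 = max(ix - halfw, 0), min(ix + halfw + 1, nx)
        y0, y1 = max(iy - halfw, 0), min(iy + halfw + 1, ny)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1) - cx
        ys = np.arange(y0, y1) - cy
        patch = np.exp(-(xs[None, :] ** 2 + ys[:, None] ** 2) / (2 * sigma ** 2))
        canvas[y0:y1, x0:x1] += amplitude * patch
    return canvas


def render_bead_images(
    scene: GroundTruthScene,
    displacement: Optional[DisplacementField] = None,
    image_shape: Optional[Tuple[int, int]] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render the relaxed reference image and the loaded frame stack.

    Loaded-frame bead centres are the reference centres plus the
    interpolated gel displacement (converted μm → px) plus the per-frame
    rigid drift.  Beads displaced outside the frame are dropped (counted in
    the log).  Returns ``(reference, stack)`` with ``reference`` a 2-D
    uint16 image and ``stack`` shaped (n_frames, ny, nx).
    """
    if displacement is None:
        displacement = forward_displacement(scene.traction_truth, scene.gel)
    px = scene.pixel_size
    width, height = scene.field_of_view
    if image_shape is None:
        image_shape = (int(round(height / px)), int(round(width / px)))
    ny, nx = image_shape
    amp = float(scene.noise.get("amplitude", 3000.0))
    bg = float(scene.noise.get("background", 100.0))
    counting = bool(scene.noise.get("counting_noise", False))
    rng = np.random.default_rng(scene.seed)

    beads = scene.bead_positions_reference
    ref_px = beads / px
    reference = _render_spots(ref_px, image_shape, scene.bead_sigma_px, amp) + bg

    interp_u = RegularGridInterpolator(
        (displacement.y, displacement.x), displacement.u,
        bounds_error=False, fill_value=0.0,
    )
    interp_v = RegularGridInterpolator(
        (displacement.y, displacement.x), displacement.v,
        bounds_error=False, fill_value=0.0,
    )
    pts = beads[:, ::-1]  # (y, x) ordering for the interpolator
    du = interp_u(pts)
    dv = interp_v(pts)

    frames = []
    for fi in range(scene.drift_per_frame.shape[0]):
        drift = scene.drift_per_frame[fi]
        loaded_px = np.column_stack(
            [
                (beads[:, 0] + du) / px + drift[0],
                (beads[:, 1] + dv) / px + drift[1],
            ]
        )
        inside = (
            (loaded_px[:, 0] >= 0)
            & (loaded_px[:, 0] < nx)
            & (loaded_px[:, 1] >= 0)
            & (loaded_px[:, 1] < ny)
        )
        dropped = int((~inside).sum())
        if dropped:
            logger.info("frame %d: %d beads displaced out of frame", fi, dropped)
        frame = _render_spots(
            loaded_px[inside], image_shape, scene.bead_sigma_px, amp
        ) + bg
        frames.append(frame)
    stack = np.stack(frames)

    if counting:
        reference = rng.poisson(reference).astype(float)
        stack = rng.poisson(stack).astype(float)
    reference = np.clip(reference, 0, 65535).astype(np.uint16)
    stack = np.clip(stack, 0, 65535).astype(np.uint16)
    return reference, stack


# ---------------------------------------------------------------------------
# peak-train force program
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakTrainSpec:
    """Parameters of a ramp-then-fluctuate max-traction time course.

    Defaults reflect the study conditions: 5-min sampling over a 4-h
    acquisition, a ~1-h adhesion ramp, and peaks recurring every ~10 min
    with ~1 min jitter on top of a stabilized baseline.
    """

    mean_period: float = 10.0       # min between peaks
    jitter_sd: float = 1.0          # min, SD of inter-peak interval
    peak_amplitude: float = 30.0    # Pa
    baseline: float = 100.0         # Pa plateau after the ramp
    ramp_duration: float = 60.0     # min
    sampling_interval: float = 5.0  # min
    duration: float = 240.0         # min
    peak_width: float = 2.0         # min, Gaussian half-width of each peak

    def __post_init__(self) -> None:
        if not self.mean_period > 0:
            raise ValueError("mean_period must be positive")
        if not self.sampling_interval > 0:
            raise ValueError("sampling_interval must be positive")
        if self.duration < self.sampling_interval:
            raise ValueError("duration must cover at least one sampling interval")


def gen_peak_series(
    spec: PeakTrainSpec, seed: int = 0
) -> Tuple[TimeSeries, np.ndarray]:
    """Generate the force program and its ground-truth peak times.

    The series is a monotone ramp from 0 to ``baseline`` over
    ``ramp_duration``, then baseline plus Gaussian-shaped peaks whose
    centres follow a renewal process with intervals
    N(mean_period, jitter_sd²) truncated at one tenth of the mean period.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, spec.duration + 0.5 * spec.sampling_interval,
                  spec.sampling_interval)
    ramp = spec.baseline * np.clip(t / max(spec.ramp_duration, 1e-12), 0.0, 1.0)
    values = ramp.copy()

    peak_times = []
    t_peak = spec.ramp_duration + spec.mean_period
    while t_peak < spec.duration:
        peak_times.append(t_peak)
        interval = spec.mean_period
        if spec.jitter_sd > 0:
            interval = rng.normal(spec.mean_period, spec.jitter_sd)
            interval = max(interval, 0.1 * spec.mean_period)
        t_peak += interval
    peak_times = np.asarray(peak_times)

    for tp in peak_times:
        values += spec.peak_amplitude * np.exp(
            -0.5 * ((t - tp) / spec.peak_width) ** 2
        )
    ts = TimeSeries(t, values, label="max traction", unit="Pa")
    return ts, peak_times


# ---------------------------------------------------------------------------
# embryo motion
# ---------------------------------------------------------------------------

def gen_trajectory(
    speed: float,
    persistence: float,
    n_steps: int,
    interval: float = 20.0,
    seed: int = 0,
    start: Tuple[float, float] = (0.0, 0.0),
) -> Trajectory:
    """Persistent random walk sampled every ``interval`` minutes.

    The heading evolves by Gaussian increments with variance 2·Δt/P where
    P is the persistence time; P = 0 gives an uncorrelated (diffusive)
    walk, P = inf a straight (ballistic) track, speed = 0 a stationary one.
    """
    if speed < 0:
        raise ValueError("speed must be non-negative")
    rng = np.random.default_rng(seed)
    times = np.arange(n_steps + 1) * interval
    pos = np.zeros((n_steps + 1, 2), dtype=float)
    pos[0] = start
    if speed == 0:
        pos[:] = start
        return Trajectory(times, pos)
    theta = rng.uniform(0, 2 * np.pi)
    step = speed * interval
    for i in range(n_steps):
        if persistence <= 0:
            theta = rng.uniform(0, 2 * np.pi)
        elif not np.isinf(persistence):
            theta += rng.normal(0.0, np.sqrt(2.0 * interval / persistence))
        pos[i + 1] = pos[i] + step * np.array([np.cos(theta), np.sin(theta)])
    return Trajectory(times, pos)


# ---------------------------------------------------------------------------
# nanoindentation
# ---------------------------------------------------------------------------

def gen_indentation_curve(
    E: float,
    nu: float = 0.5,
    R: float = 3.0,
    contact_offset: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    max_depth: float = 2.0,
    n_samples: int = 200,
) -> IndentationCurve:
    """Hertzian force–indentation curve for a spherical tip.

    F(δ) = (4/3)·E/(1−ν²)·√R·δ_eff^{3/2} with δ_eff = max(δ − offset, 0);
    zero-force baseline before contact.  ``noise_sd`` is additive Gaussian
    force noise in nN.  Defaults match a 3.000 μm radius tip on ν = 0.5
    material.
    """
    if E <= 0 or R <= 0:
        raise ValueError("E and R must be positive")
    delta = np.linspace(0.0, contact_offset + max_depth, n_samples)
    force = hertz_force(delta - contact_offset, E, nu, R)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        force = force + rng.normal(0.0, noise_sd, size=force.shape)
    return IndentationCurve(delta=delta, force=force, tip_radius=R)


# ---------------------------------------------------------------------------
# YAP two-channel cell images
# ---------------------------------------------------------------------------

def gen_yap_cell_image(
    nuc_mean_intensity: float,
    cyto_mean_intensity: float,
    nucleus_mask: np.ndarray,
    cell_mask: np.ndarray,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> Tuple[np.ndarray, dict]:
    """Two-channel (nucleus marker, YAP) image with prescribed region means.

    The YAP channel takes ``nuc_mean_intensity`` inside the nucleus and
    ``cyto_mean_intensity`` over the rest of the cell.  Returns the (2, H, W)
    image stack and a dict with the analytic ground truth:
    ``ratio`` = (nuc_mean·A_nuc) / (cyto_mean·(A_cell − A_nuc)), flagged
    ``degenerate`` when the cytoplasmic signal is zero.
    """
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if nucleus_mask.shape != cell_mask.shape:
        raise ValueError("masks must share a shape")
    if np.any(nucleus_mask & ~cell_mask):
        raise ValueError("nucleus mask must be a subset of the cell mask")
    if not nucleus_mask.any() or not (cell_mask & ~nucleus_mask).any():
        raise ValueError("nucleus and cytoplasm regions must both be nonempty")

    yap = np.zeros(cell_mask.shape, dtype=float)
    yap[cell_mask] = cyto_mean_intensity
    yap[nucleus_mask] = nuc_mean_intensity
    nuc_channel = np.zeros_like(yap)
    nuc_channel[nucleus_mask] = 1000.0
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        yap = yap + rng.normal(0.0, noise_sd, size=yap.shape)

    a_nuc = int(nucleus_mask.sum())
    a_cyto = int((cell_mask & ~nucleus_mask).sum())
    nuc_density = nuc_mean_intensity * a_nuc
    cyto_density = cyto_mean_intensity * a_cyto
    truth = {
        "nuc_density": nuc_density,
        "cyto_density": cyto_density,
        "degenerate": cyto_density == 0.0,
        "ratio": np.inf if cyto_density == 0 else nuc_density / cyto_density,
    }
    return np.stack([nuc_channel, yap]), truth
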