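"""End-to-end orchestration: register → displace → invert → dynamics.

``run_pipeline`` consumes either on-disk bead images (a relaxed reference
TIFF plus a loaded stack) or a synthetic scene generated from the config
seed, and writes a run directory with drift, displacement, traction and
per-frame force-metric tables, each stamped with the config hash.
Identical config + seed gives identical outputs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from . import io
from .config import RunConfig, validate_config
from .displacement import compute_displacement_field, filter_outliers
from .dynamics import detect_peaks
from .fields import GelProperties, TractionField
from .registration import estimate_drift, apply_shift
from .series import TimeSeries
from .synthetic import forward_displacement, make_scene, render_bead_images
from .traction import fttc_inverse, noise_floor, select_lambda, traction_metrics

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    out_dir: Path
    metrics: pd.DataFrame
    tractions: List[TractionField]
    config_hash: str
    ground_truth_max: Optional[float] = None  # Pa, synthetic runs only


def _contact_mask_from_noise(traction: TractionField) -> np.ndarray:
    """Threshold fallback when no embryo mask is supplied.

    Uses the outer 15% border of the field as the embryo-free background
    region and keeps nodes above its mean + 2·SD traction.
    """
    ny, nx = traction.tx.shape
    by = max(int(0.15 * ny), 1)
    bx = max(int(0.15 * nx), 1)
    bg = np.zeros((ny, nx), dtype=bool)
    bg[:by, :] = bg[-by:, :] = True
    bg[:, :bx] = bg[:, -bx:] = True
    floor = noise_floor(traction, bg)
    mask = traction.magnitude > floor
    if not mask.any():  # degenerate: keep the strongest node
        mask = traction.magnitude >= traction.magnitude.max()
    return mask


def run_pipeline(
    config: RunConfig,
    out_dir: Union[str, Path],
    reference_path: Optional[Union[str, Path]] = None,
    stack_path: Optional[Union[str, Path]] = None,
    contact_mask: Optional[np.ndarray] = None,
) -> PipelineResult:
    """Execute the TFM pipeline and write a run directory.

    Without ``reference_path``/``stack_path`` a synthetic scene is
    generated from the config seed (simulation mode).  A missing reference
    is an error: displacements are defined against the relaxed bead image
    acquired after embryo removal.
    """
    issues = [i for i in validate_config(config) if not i.startswith("Nyquist")]
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    prov = {"config_hash": chash, "package": "embryotfm"}
    gel = GelProperties(config.youngs_modulus, config.poisson_ratio,
                        config.thickness)

    truth_max: Optional[float] = None
    if reference_path is None and stack_path is None:
        scene = make_scene(seed=config.seed, gel=gel, n_frames=config.n_frames,
                           pixel_size=config.pixel_size)
        reference, stack = render_bead_images(scene)
        truth_max = float(scene.traction_truth.magnitude.max())
        io.write_tiff(out_dir / "reference.tif", reference)
        io.write_tiff(out_dir / "stack.tif", stack)
        io.write_gel_json(out_dir / "gel.json", gel, seed=config.seed,
                          pixel_size_um=config.pixel_size)
    elif reference_path is None:
        raise ValueError(
            "missing relaxed reference image: displacements are measured "
            "against the bead image acquired after embryo removal"
        )
    else:
        reference = io.read_tiff(reference_path)
        stack = io.read_tiff(stack_path) if stack_path else None
        if stack is None:
            raise ValueError("missing loaded bead image stack")
        if stack.ndim == 2:
            stack = stack[None]

    # --- register: drift relative to the relaxed reference -----------------
    frames = [reference] + [stack[i] for i in range(stack.shape[0])]
    template = tuple(config.template) if config.template else None
    track = estimate_drift(frames, template=template,
                           reference_index=config.reference_frame,
                           score_floor=config.score_floor)
    corrected = [apply_shift(stack[i], track.shifts[i + 1])
                 for i in range(stack.shape[0])]
    io.write_csv(
        out_dir / "drift.csv",
        pd.DataFrame(
            {
                "frame": np.arange(len(frames)),
                "dx_px": track.shifts[:, 0],
                "dy_px": track.shifts[:, 1],
                "score": track.scores,
            }
        ),
        prov,
    )

    # --- displace, invert, measure per frame -------------------------------
    rows = []
    tractions: List[TractionField] = []
    for fi, frame in enumerate(corrected):
        field = compute_displacement_field(
            frame, reference,
            window_size=config.window_size,
            overlap=config.overlap,
            pixel_size=config.pixel_size,
        )
        field, _ = filter_outliers(field, threshold=config.outlier_threshold)
        if config.lambda_strategy == "fixed":
            lam = float(config.lambda_value)
        elif config.lambda_strategy == "noise":
            ny, nx = field.u.shape
            bg = np.zeros((ny, nx), dtype=bool)
            by, bx = max(int(0.15 * ny), 1), max(int(0.15 * nx), 1)
            bg[:by, :] = bg[-by:, :] = True
            bg[:, :bx] = bg[:, -bx:] = True
            lam = select_lambda(field, gel, strategy="noise", noise_region=bg,
                                filter_mode=config.filter_mode)
        else:
            lam = select_lambda(field, gel, strategy=config.lambda_strategy,
                                filter_mode=config.filter_mode)
        traction = fttc_inverse(field, gel, lam=lam,
                                filter_mode=config.filter_mode,
                                pad_factor=config.pad_factor)
        tractions.append(traction)
        mask = contact_mask if contact_mask is not None \
            else _contact_mask_from_noise(traction)
        m = traction_metrics(traction, mask, time=fi * config.frame_interval)
        rows.append(
            {
                "t_min": m.time,
                "max_pa": m.max_traction,
                "mean_pa": m.mean_traction,
                "area_um2": m.contact_area,
                "total_nn": m.total_force,
                "lambda": lam,
            }
        )
        io.write_csv(out_dir / f"displacement_{fi:03d}.csv",
                     io.displacement_to_frame(field), prov)
        io.write_csv(out_dir / f"traction_{fi:03d}.csv",
                     io.traction_to_frame(traction), prov)

    metrics = pd.DataFrame(rows)
    io.write_csv(out_dir / "metrics.csv", metrics, prov)

    # --- dynamics: peaks of the max-traction series -------------------------
    if len(metrics) >= 3:
        series = TimeSeries(metrics["t_min"].to_numpy(),
                            metrics["max_pa"].to_numpy(),
                            label="max traction", unit="Pa")
        peaks = detect_peaks(series)
        io.write_csv(
            out_dir / "peaks.csv",
            pd.DataFrame({"peak_time_min": peaks.peak_times,
                          "peak_pa": peaks.peak_heights}),
            prov,
        )
    logger.info("pipeline run complete: %s (config %s)", out_dir, chash)
    return PipelineResult(out_dir, metrics, tractions, chash, truth_max)
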