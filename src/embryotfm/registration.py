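"""Rigid stage-drift compensation for bead image time series.

Multi-position time-lapse imaging introduces rigid stage drift that would
otherwise masquerade as gel deformation.  Drift is estimated per frame by
phase cross-correlation against a reference frame (full frame by default,
or a user template region reproducing the classic template-matching
workflow) with Fourier-upsampled subpixel refinement, and removed by
bilinear resampling.

Shifts are expressed as (dx, dy) in pixels: frame content displaced by
+shift relative to the reference.  ``apply_shift(frame, shift)`` resamples
by the negated shift, i.e. removes the drift.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

logger = logging.getLogger(__name__)

__all__ = ["DriftTrack", "estimate_drift", "apply_shift", "register_stack"]


@dataclass
class DriftTrack:
    """Per-frame rigid shifts (dx, dy) in px relative to a reference frame."""

    shifts: np.ndarray          # (n_frames, 2) as (dx, dy)
    reference_index: int
    scores: np.ndarray          # normalized correlation per frame
    flagged: np.ndarray         # frames whose shift was interpolated

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        self.flagged = np.asarray(self.flagged, dtype=bool)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError("shifts must have shape (n_frames, 2)")
        if not np.allclose(self.shifts[self.reference_index], 0.0):
            raise ValueError("shift of the reference frame must be (0, 0)")


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of two equal-shape images."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.sum(a * b) / denom)


def estimate_drift(
    stack: Sequence[np.ndarray],
    template: Optional[Tuple[int, int, int, int]] = None,
    reference_index: int = 0,
    upsample_factor: int = 100,
    score_floor: float = 0.2,
) -> DriftTrack:
    """Estimate per-frame rigid drift against the reference frame.

    Parameters
    ----------
    stack : sequence of 2-D arrays
        Image time series (≥ 2 frames, identical shapes).
    template : (x, y, w, h), optional
        Restrict correlation to this region (must lie inside the frame);
        default is the full frame.
    reference_index : int
        Frame shifts are reported relative to this frame (shift (0, 0)).
    upsample_factor : int
        Fourier upsampling for subpixel refinement (100 → 0.01 px grid).
    score_floor : float
        Frames whose post-alignment correlation falls below this floor are
        flagged and their shift replaced by interpolation from neighboring
        frames.
    """
    frames = [np.asarray(f, dtype=float) for f in stack]
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("all frames must share a shape")

    def crop(img: np.ndarray) -> np.ndarray:
        if template is None:
            return img
        x, y, w, h = template
        if x < 0 or y < 0 or x + w > shape[1] or y + h > shape[0] or w < 2 or h < 2:
            raise ValueError("template region must lie inside the frame")
        return img[y: y + h, x: x + w]

    ref = crop(frames[reference_index])
    if float(ref.std()) == 0.0:
        raise ValueError("flat (zero-variance) template")

    n = len(frames)
    shifts = np.zeros((n, 2), dtype=float)
    scores = np.ones(n, dtype=float)
    for i, frame in enumerate(frames):
        if i == reference_index:
            continue
        moving = crop(frame)
        # returned (row, col) shift registers `moving` onto `ref`, i.e. it
        # is minus the displacement of the frame content
        (drow, dcol), _, _ = phase_cross_correlation(
            ref, moving, upsample_factor=upsample_factor, normalization=None
        )
        shifts[i] = (-dcol, -drow)
        aligned = ndimage.shift(moving, (drow, dcol), order=1, mode="nearest")
        scores[i] = _ncc(ref, aligned)

    flagged = scores < score_floor
    flagged[reference_index] = False
    if flagged.any():
        good = ~flagged
        idx = np.arange(n)
        for c in range(2):
            shifts[flagged, c] = np.interp(idx[flagged], idx[good], shifts[good, c])
        logger.info("interpolated drift for %d low-correlation frames",
                    int(flagged.sum()))
    return DriftTrack(shifts, reference_index, scores, flagged)


def apply_shift(
    image: np.ndarray,
    shift: Tuple[float, float],
    order: int = 1,
    background: Optional[float] = None,
) -> np.ndarray:
    """Resample an image by the negated (dx, dy) shift (drift removal).

    ``order=1`` is bilinear; ``order=3`` bicubic.  Out-of-frame pixels are
    filled with ``background`` (default: the image median, a robust
    estimate of the background level).
    """
    dx, dy = shift
    if not (np.isfinite(dx) and np.isfinite(dy)):
        raise ValueError("shift must be finite")
    img = np.asarray(image, dtype=float)
    if background is None:
        background = float(np.median(img))
    return ndimage.shift(img, (-dy, -dx), order=order, mode="constant",
                         cval=background)


def register_stack(
    stack: Sequence[np.ndarray],
    track: Optional[DriftTrack] = None,
    **kwargs,
) -> Tuple[np.ndarray, DriftTrack]:
    """Estimate drift (unless given) and return the corrected stack."""
    if track is None:
        track = estimate_drift(stack, **kwargs)
    corrected = np.stack(
        [apply_shift(f, track.shifts[i]) for i, f in enumerate(stack)]
    )
    return corrected, track
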