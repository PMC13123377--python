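"""Nuclear-to-cytoplasmic YAP ratio from ROI-integrated densities.

The mechanosensitive transcriptional regulator YAP shuttles between
nucleus and cytoplasm in response to substrate stiffness.  Its
partitioning is quantified from a YAP fluorescence channel with a nucleus
ROI (from a DNA stain) and a whole-cell ROI (from the actin cytoskeleton):

    YAP_Cyto    = YAP_Cell − YAP_Nuc
    YAP_Nuc/Cyto = YAP_Nuc / YAP_Cyto

where each term is the integrated density (sum of pixel intensities) over
the ROI.  The cytoplasmic signal is defined by subtraction of densities,
not by a cytoplasm mask; a mask-based alternative is available but
non-default.  The ratio is invariant to multiplicative intensity scaling
but not to additive offsets, so optional background subtraction with a
user-stated background ROI is provided (off by default).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["YapMeasurement", "integrated_density", "yap_ratio", "measure_cell"]


@dataclass
class YapMeasurement:
    """Per-cell integrated densities (a.u.) and the Nuc/Cyto ratio."""

    yap_cell: float
    yap_nuc: float
    yap_cyto: float
    ratio: float
    cell_id: Optional[int] = None
    degenerate: bool = False  # True when the cytoplasmic density is zero


def integrated_density(
    image: np.ndarray,
    roi_mask: np.ndarray,
    background_mask: Optional[np.ndarray] = None,
) -> float:
    """Sum of pixel intensities over an ROI, optionally background-subtracted.

    With a background ROI, its mean intensity is subtracted from every
    pixel before summing: (Σ I) − mean(background) × area(ROI).
    """
    image = np.asarray(image, dtype=float)
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.shape != image.shape:
        raise ValueError("ROI mask must match the image shape")
    if not roi.any():
        raise ValueError("empty ROI mask")
    total = float(image[roi].sum())
    if background_mask is not None:
        bg = np.asarray(background_mask, dtype=bool)
        if not bg.any():
            raise ValueError("empty background mask")
        total -= float(image[bg].mean()) * roi.sum()
    return total


def yap_ratio(
    cell_density: float,
    nuc_density: float,
    cell_id: Optional[int] = None,
) -> YapMeasurement:
    """Nuc/Cyto ratio from whole-cell and nuclear integrated densities."""
    if nuc_density > cell_density:
        raise ValueError(
            "nuclear density exceeds cell density — nucleus ROI outside the "
            "cell signal (upstream segmentation fault)"
        )
    cyto = cell_density - nuc_density
    if cyto == 0:
        return YapMeasurement(cell_density, nuc_density, 0.0, np.inf,
                              cell_id, degenerate=True)
    return YapMeasurement(cell_density, nuc_density, cyto,
                          nuc_density / cyto, cell_id)


def measure_cell(
    yap_channel: np.ndarray,
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    cell_id: Optional[int] = None,
    background_mask: Optional[np.ndarray] = None,
    cyto_from_mask: bool = False,
) -> YapMeasurement:
    """Full per-cell measurement from a YAP channel and paired ROI masks.

    ``cyto_from_mask=True`` switches to the mask-based alternative where
    the cytoplasmic density is summed directly over cell − nucleus pixels
    (identical for nucleus ⊂ cell masks; differs when they disagree).
    """
    nucleus = np.asarray(nucleus_mask, dtype=bool)
    cell = np.asarray(cell_mask, dtype=bool)
    if np.any(nucleus & ~cell):
        raise ValueError("nucleus mask must lie inside the cell mask")
    cell_d = integrated_density(yap_channel, cell, background_mask)
    nuc_d = integrated_density(yap_channel, nucleus, background_mask)
    if cyto_from_mask:
        cyto_d = integrated_density(yap_channel, cell & ~nucleus, background_mask)
        meas = yap_ratio(cyto_d + nuc_d, nuc_d, cell_id)
    else:
        meas = yap_ratio(cell_d, nuc_d, cell_id)
    return meas
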