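"""Fourier-space Boussinesq elasticity kernel for a linear half-space.

Surface tractions T(x, y) applied to an incompressible-to-compressible
(0 ≤ ν ≤ 0.5) linear-elastic half-space produce surface displacements
u(x, y) through a convolution with the Boussinesq Green's function.  Per
wavevector k = (kx, ky), |k| = k, the 2×2 kernel is

    G̃(k) = 2(1+ν) / (E k³) · [ (1−ν)k² + ν ky²,   −ν kx ky
                                −ν kx ky,           (1−ν)k² + ν kx² ]

so that ũ = G̃ T̃.  The k = 0 mode is undefined (a uniform traction on an
infinite half-space gives unbounded displacement) and is set to zero, which
removes rigid translation and enforces zero net force.

Units: lengths μm, stresses Pa, so G̃ carries μm/Pa and displacements come
out in μm.  The half-space (infinite-thickness) approximation is standard
for TFM on gels whose thickness (~150 μm) far exceeds the bead
displacements (a few μm).
"""
from __future__ import annotations

from typing import Tuple

import numpy as np

from .fields import GelProperties

__all__ = ["kernel_components", "wavevectors", "pad_field", "crop_field"]


def wavevectors(ny: int, nx: int, spacing: float) -> Tuple[np.ndarray, np.ndarray]:
    """Angular wavevector meshes (rad/μm) for an (ny, nx) grid."""
    kx = 2.0 * np.pi * np.fft.fftfreq(nx, d=spacing)
    ky = 2.0 * np.pi * np.fft.fftfreq(ny, d=spacing)
    return np.meshgrid(kx, ky)


def kernel_components(
    kx: np.ndarray, ky: np.ndarray, gel: GelProperties
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (Gxx, Gxy, Gyy) of the Boussinesq kernel; k = 0 entries are 0."""
    E = gel.youngs_modulus
    nu = gel.poisson_ratio
    k2 = kx * kx + ky * ky
    k = np.sqrt(k2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = 2.0 * (1.0 + nu) / (E * k ** 3)
        gxx = pref * ((1.0 - nu) * k2 + nu * ky * ky)
        gyy = pref * ((1.0 - nu) * k2 + nu * kx * kx)
        gxy = -pref * nu * kx * ky
    zero = k2 == 0.0
    for g in (gxx, gxy, gyy):
        g[zero] = 0.0
    return gxx, gxy, gyy


def pad_field(
    comp: np.ndarray, pad_factor: int, taper: bool = True
) -> np.ndarray:
    """Embed a component in a pad_factor× larger array.

    The original data occupy the top-left block unchanged.  The pad region
    is filled with a cosine decay from the edge values down to zero, which
    keeps the periodic extension continuous without touching the data.
    With ``taper=False`` the pad region is plain zeros (appropriate for
    compactly supported fields such as tractions).
    """
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    if pad_factor == 1:
        return comp.copy()
    ny, nx = comp.shape
    NY, NX = ny * pad_factor, nx * pad_factor
    out = np.zeros((NY, NX), dtype=float)
    out[:ny, :nx] = comp
    if taper:
        # decay right edge -> 0 across the pad strip, then bottom edge
        wx = nx * (pad_factor - 1)
        ramp_x = 0.5 * (1.0 + np.cos(np.pi * (np.arange(1, wx + 1) / (wx + 1))))
        out[:ny, nx:] = comp[:, -1][:, None] * ramp_x[None, :]
        wy = ny * (pad_factor - 1)
        ramp_y = 0.5 * (1.0 + np.cos(np.pi * (np.arange(1, wy + 1) / (wy + 1))))
        out[ny:, :] = out[ny - 1, :][None, :] * ramp_y[:, None]
    return out


def crop_field(comp: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    """Crop the top-left ``shape`` block (inverse of :func:`pad_field`)."""
    return comp[: shape[0], : shape[1]].copy()
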