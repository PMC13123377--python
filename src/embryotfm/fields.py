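"""Core containers: gel properties and vector fields on regular grids.

All spatial quantities are carried in micrometres (μm) and stresses in
pascals (Pa).  Fields live on uniform 2-D grids with node coordinates given
by 1-D axis vectors ``x`` (columns) and ``y`` (rows); component arrays are
indexed ``[row, col]`` i.e. ``[y, x]``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["GelProperties", "DisplacementField", "TractionField"]


def _check_uniform(axis: np.ndarray, name: str) -> float:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 3:
        raise ValueError(f"{name} must be a 1-D axis with at least 3 nodes")
    d = np.diff(axis)
    if d[0] <= 0 or not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{name} must be uniformly increasing")
    return float(d[0])


@dataclass(frozen=True)
class GelProperties:
    """Linear-elastic substrate parameters.

    Parameters
    ----------
    youngs_modulus : float
        Young's modulus E in Pa.  The soft hydrogels used for embryo culture
        span roughly 1–50 kPa.
    poisson_ratio : float
        Poisson's ratio ν, dimensionless in [0, 0.5].  Hydrated gels are
        conventionally treated as incompressible (ν = 0.5).
    thickness : float
        Gel thickness in μm.  Informational: the elastic model treats the
        gel as a half-space, valid because thickness ≫ bead displacement.
    """

    youngs_modulus: float
    poisson_ratio: float = 0.5
    thickness: float = 150.0

    def __post_init__(self) -> None:
        if not self.youngs_modulus > 0:
            raise ValueError("youngs_modulus must be positive")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5]")


@dataclass
class DisplacementField:
    """Gel surface displacement sampled on a regular grid.

    ``u`` is the x-component and ``v`` the y-component of displacement in
    μm, measured loaded-relative-to-relaxed (bead position with the embryo
    attached minus position after embryo removal).
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    mask: Optional[np.ndarray] = None
    quality: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        dx = _check_uniform(self.x, "x")
        dy = _check_uniform(self.y, "y")
        if not np.isclose(dx, dy, rtol=1e-6):
            raise ValueError("grid spacing must be equal in x and y")
        shape = (self.y.size, self.x.size)
        for name in ("u", "v"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} must have shape (ny, nx) = {shape}")
        if self.mask is None:
            self.mask = np.ones(shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if not np.all(np.isfinite(self.u[self.mask])) or not np.all(
            np.isfinite(self.v[self.mask])
        ):
            raise ValueError("u, v must be finite on valid nodes")

    @property
    def spacing(self) -> float:
        """Grid spacing in μm."""
        return float(self.x[1] - self.x[0])

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def copy(self) -> "DisplacementField":
        return DisplacementField(
            self.x.copy(), self.y.copy(), self.u.copy(), self.v.copy(),
            None if self.mask is None else self.mask.copy(),
            None if self.quality is None else np.array(self.quality),
        )


@dataclass
class TractionField:
    """Traction stress vectors (Pa) on a regular grid.

    ``lam`` records the regularization parameter used in the inverse
    reconstruction that produced the field (None for ground truth).
    """

    x: np.ndarray
    y: np.ndarray
    tx: np.ndarray
    ty: np.ndarray
    lam: Optional[float] = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.tx = np.asarray(self.tx, dtype=float)
        self.ty = np.asarray(self.ty, dtype=float)
        dx = _check_uniform(self.x, "x")
        dy = _check_uniform(self.y, "y")
        if not np.isclose(dx, dy, rtol=1e-6):
            raise ValueError("grid spacing must be equal in x and y")
        shape = (self.y.size, self.x.size)
        for name in ("tx", "ty"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} must have shape (ny, nx) = {shape}")

    @property
    def spacing(self) -> float:
        """Grid spacing in μm."""
        return float(self.x[1] - self.x[0])

    @property
    def magnitude(self) -> np.ndarray:
        """|T| = sqrt(Tx² + Ty²) per node, Pa."""
        return np.hypot(self.tx, self.ty)

    @property
    def node_area(self) -> float:
        """Area associated with one grid node, μm²."""
        return self.spacing ** 2

    def net_force_imbalance(self) -> float:
        """|Σ T·dA| / Σ |T|·dA, dimensionless force-balance defect."""
        fx = float(np.sum(self.tx))
        fy = float(np.sum(self.ty))
        total = float(np.sum(self.magnitude))
        if total == 0.0:
            return 0.0
        return float(np.hypot(fx, fy) / total)
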