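"""Hertzian spherical-contact analysis of force–indentation curves.

Young's modulus is extracted from nanoindentation curves with the Hertz
model for a rigid spherical tip on an elastic half-space,

    F(δ) = (4/3) · E/(1−ν²) · √R · δ^{3/2},

with F in nN, δ and R in μm and E in Pa (1 Pa·μm² = 10⁻³ nN).  The contact
point is fitted jointly with E, which is robust on soft samples where
contact is gradual.  Curves with irregular shapes (adhesion dips,
non-monotone loading, baseline drift, no contact) are flagged for
exclusion before group averaging.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import List, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

PA_UM2_TO_NN = 1e-3  # 1 Pa·μm² = 1e-12 N = 1e-3 nN

__all__ = [
    "IndentationCurve",
    "HertzFit",
    "hertz_force",
    "fit_hertz",
    "qc_curve",
    "summarize_points",
]


def hertz_force(delta: np.ndarray, E: float, nu: float, R: float) -> np.ndarray:
    """Hertz force in nN at indentation depth ``delta`` (μm, may be < 0).

    Negative depths (pre-contact) give zero force.
    """
    d = np.clip(np.asarray(delta, dtype=float), 0.0, None)
    return (4.0 / 3.0) * (E / (1.0 - nu ** 2)) * np.sqrt(R) * d ** 1.5 * PA_UM2_TO_NN


@dataclass
class IndentationCurve:
    """Force (nN) vs indentation depth (μm) samples plus tip metadata."""

    delta: np.ndarray
    force: np.ndarray
    tip_radius: float = 3.0
    cantilever_stiffness: Optional[float] = None  # N/m, informational

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.delta.shape != self.force.shape or self.delta.ndim != 1:
            raise ValueError("delta and force must be 1-D arrays of equal length")
        if np.any(np.diff(self.delta) < 0):
            raise ValueError("samples must be ordered by increasing delta")
        if not (np.all(np.isfinite(self.delta)) and np.all(np.isfinite(self.force))):
            raise ValueError("delta and force must be finite")


@dataclass
class HertzFit:
    youngs_modulus: float            # Pa
    contact_offset: float            # μm
    rmse: float                      # nN
    r_squared: float
    qc_pass: bool
    reasons: List[str] = dc_field(default_factory=list)


def _baseline_noise(curve: IndentationCurve) -> float:
    """SD of the pre-contact force baseline (first fifth of the curve)."""
    n = max(5, curve.force.size // 5)
    return float(np.std(curve.force[:n]))


def fit_hertz(
    curve: IndentationCurve,
    R: Optional[float] = None,
    nu: float = 0.5,
    thickness: Optional[float] = None,
) -> HertzFit:
    """Joint least-squares fit of (E, contact offset) to a Hertz curve.

    When ``thickness`` (μm) is given, samples indenting deeper than 10% of
    it are excluded from the fit (thin-sample validity limit of the Hertz
    model).
    """
    if R is None:
        R = curve.tip_radius
    if R <= 0:
        raise ValueError("tip radius must be positive")
    if not 0.0 <= nu <= 0.5:
        raise ValueError("poisson ratio must lie in [0, 0.5]")
    if curve.delta.size < 10:
        raise ValueError("need at least 10 samples spanning past contact")

    delta = curve.delta
    force = curve.force
    f_max = float(np.max(np.abs(force)))
    noise = _baseline_noise(curve)
    if f_max <= max(3.0 * noise, 1e-12):
        return HertzFit(np.nan, np.nan, np.nan, np.nan, False, ["non_contact"])

    # initial guesses: contact where force first exceeds the noise band,
    # modulus from the final point
    above = np.nonzero(force > 3.0 * noise)[0]
    d0_init = delta[above[0]] if above.size else delta[delta.size // 2]
    d_eff_end = max(delta[-1] - d0_init, 1e-6)
    k_end = force[-1] / (d_eff_end ** 1.5)
    E_init = max(
        k_end / ((4.0 / 3.0) / (1.0 - nu ** 2) * np.sqrt(R) * PA_UM2_TO_NN), 1.0
    )

    sel = np.ones_like(delta, dtype=bool)

    def residuals(p: np.ndarray) -> np.ndarray:
        E, d0 = p
        return hertz_force(delta[sel] - d0, E, nu, R) - force[sel]

    for _ in range(2):
        try:
            res = least_squares(
                residuals,
                x0=[E_init, d0_init],
                bounds=([1e-9, delta[0] - (delta[-1] - delta[0])], [np.inf, delta[-1]]),
            )
        except Exception as exc:  # pragma: no cover - scipy failure path
            return HertzFit(np.nan, np.nan, np.nan, np.nan, False,
                            [f"fit_failed:{exc}"])
        E_fit, d0_fit = res.x
        if thickness is None:
            break
        new_sel = (delta - d0_fit) <= 0.1 * thickness
        if new_sel.sum() < 10 or np.array_equal(new_sel, sel):
            break
        sel = new_sel
        E_init, d0_init = E_fit, d0_fit

    if not res.success or E_fit <= 0:
        return HertzFit(np.nan, np.nan, np.nan, np.nan, False, ["fit_not_converged"])

    pred = hertz_force(delta[sel] - d0_fit, E_fit, nu, R)
    resid = pred - force[sel]
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    ss_tot = float(np.sum((force[sel] - force[sel].mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else np.nan
    qc = qc_curve(curve)
    return HertzFit(float(E_fit), float(d0_fit), rmse, r2, not qc, qc)


def qc_curve(
    curve: IndentationCurve,
    noise_multiple: float = 3.0,
    drift_multiple: float = 3.0,
) -> List[str]:
    """Flag irregular curves (improper tip-sample contact).

    Returns a list of reason codes; an empty list means the curve is clean.
    Checks: overall contact (signal above the noise band), adhesion dips
    (negative excursions beyond the band), non-monotone loading past
    contact, and pre-contact baseline drift.
    """
    flags: List[str] = []
    force = curve.force
    noise = _baseline_noise(curve)
    band = max(noise_multiple * noise, 1e-12)

    if float(np.max(np.abs(force))) <= band:
        return ["non_contact"]
    if float(np.min(force)) < -band:
        flags.append("adhesion_dip")

    # baseline drift: linear trend over the pre-contact fifth
    n = max(5, force.size // 5)
    if n >= 3:
        slope = np.polyfit(curve.delta[:n], force[:n], 1)[0]
        drift = abs(slope) * (curve.delta[n - 1] - curve.delta[0])
        if drift > drift_multiple * max(noise, 1e-12):
            flags.append("baseline_drift")

    # non-monotone loading: a drop below the running max beyond the band
    contact = np.nonzero(force > band)[0]
    if contact.size:
        seg = force[contact[0]:]
        drop = np.maximum.accumulate(seg) - seg
        if float(np.max(drop)) > 2.0 * band:
            flags.append("non_monotone")
    return flags


@dataclass
class ModulusSummary:
    mean: float        # Pa
    sem: float         # Pa
    n_included: int
    n_excluded: int


def summarize_points(fits: Sequence[HertzFit]) -> ModulusSummary:
    """Mean ± SEM Young's modulus over QC-passing fits.

    Mirrors the per-sample averaging of ≥10 indentation points after
    excluding irregular curves.
    """
    passing = [f.youngs_modulus for f in fits if f.qc_pass]
    n_excl = len(fits) - len(passing)
    if not passing:
        raise ValueError("no passing fits to summarize")
    arr = np.asarray(passing, dtype=float)
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return ModulusSummary(float(arr.mean()), sem, arr.size, n_excl)
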