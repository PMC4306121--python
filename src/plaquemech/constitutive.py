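"""Yeoh hyperelastic constitutive model for incompressible planar shear.

The Yeoh strain energy function is a third-order reduced polynomial in the
first invariant of the right Cauchy-Green tensor,

    W(I1) = C10 (I1 - 3) + C20 (I1 - 3)^2 + C30 (I1 - 3)^3,

with stress-like coefficients Ci0 in MPa. It depends on I1 only, which makes
it identifiable from a single uniaxial planar-shear (pure shear) test, where
the principal stretches are (lam, 1, 1/lam) and

    I1 = lam^2 + 1 + lam^-2.

For an incompressible material the loading-direction Cauchy stress in planar
shear is

    sigma = 2 (lam^2 - lam^-2) dW/dI1.

All stresses are Cauchy (true) stresses in MPa; stretches are dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from numpy.typing import ArrayLike

__all__ = [
    "YeohCoefficients",
    "StabilityResult",
    "first_invariant_planar_shear",
    "strain_energy",
    "dpsi_di1",
    "d2psi_di1_sq",
    "cauchy_stress_planar_shear",
    "stress_tangent_planar_shear",
    "drucker_stability_check",
]

# stretches within I1_TOL of the identity are treated as undeformed
_I1_TOL = 1e-12


@dataclass(frozen=True)
class YeohCoefficients:
    """Material coefficients (C10, C20, C30) of the Yeoh model, in MPa.

    C10 must be positive (it is the small-strain shear stiffness, mu = 2*C10);
    C20 may be negative, which produces the initial softening seen in heavily
    diseased tissue.
    """

    c10: float
    c20: float
    c30: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("c10", "c20", "c30"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.c10 <= 0:
            raise ValueError(f"c10 must be positive, got {self.c10!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.c10, self.c20, self.c30], dtype=float)


class StabilityResult(NamedTuple):
    stable: bool
    first_violation: float | None


def _validate_stretch(stretch: ArrayLike) -> np.ndarray:
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    return lam


def _validate_i1(i1: ArrayLike) -> np.ndarray:
    x = np.asarray(i1, dtype=float)
    if np.any(x < 3.0 - _I1_TOL):
        raise ValueError("first invariant must be >= 3")
    return np.maximum(x, 3.0)


def first_invariant_planar_shear(stretch: ArrayLike) -> np.ndarray | float:
    """First invariant I1 = lam^2 + 1 + lam^-2 for planar-shear kinematics.

    Symmetric under lam <-> 1/lam and minimised (I1 = 3) at the identity.
    """
    lam = _validate_stretch(stretch)
    out = lam**2 + 1.0 + lam**-2
    return out if out.ndim else float(out)


def strain_energy(i1: ArrayLike, coeffs: YeohCoefficients) -> np.ndarray | float:
    """Strain energy density W(I1) in MPa; zero at the undeformed state I1 = 3."""
    x = _validate_i1(i1) - 3.0
    out = x * (coeffs.c10 + x * (coeffs.c20 + x * coeffs.c30))
    return out if out.ndim else float(out)


def dpsi_di1(i1: ArrayLike, coeffs: YeohCoefficients) -> np.ndarray | float:
    """dW/dI1 = C10 + 2 C20 (I1-3) + 3 C30 (I1-3)^2, in MPa."""
    x = _validate_i1(i1) - 3.0
    out = coeffs.c10 + x * (2.0 * coeffs.c20 + 3.0 * coeffs.c30 * x)
    return out if out.ndim else float(out)


def d2psi_di1_sq(i1: ArrayLike, coeffs: YeohCoefficients) -> np.ndarray | float:
    """Second derivative d2W/dI1^2 = 2 C20 + 6 C30 (I1-3), in MPa."""
    x = _validate_i1(i1) - 3.0
    out = 2.0 * coeffs.c20 + 6.0 * coeffs.c30 * x
    return out if out.ndim else float(out)


def cauchy_stress_planar_shear(
    stretch: ArrayLike, coeffs: YeohCoefficients
) -> np.ndarray | float:
    """Loading-direction Cauchy stress sigma = 2 (lam^2 - lam^-2) dW/dI1 (MPa).

    Zero at lam = 1; tension (positive) for lam > 1, compression for lam < 1.
    """
    lam = _validate_stretch(stretch)
    i1 = lam**2 + 1.0 + lam**-2
    out = 2.0 * (lam**2 - lam**-2) * dpsi_di1(i1, coeffs)
    return out if out.ndim else float(out)


def stress_tangent_planar_shear(
    stretch: ArrayLike, coeffs: YeohCoefficients
) -> np.ndarray | float:
    """Analytic tangent stiffness d(sigma)/d(lam) of the planar-shear stress.

    With g(lam) = lam^2 - lam^-2 and I1(lam) = lam^2 + 1 + lam^-2,

        d(sigma)/d(lam) = 2 g' W'(I1) + 2 g W''(I1) dI1/dlam,

    where g' = 2 lam + 2 lam^-3 and dI1/dlam = 2 lam - 2 lam^-3.
    """
    lam = _validate_stretch(stretch)
    i1 = lam**2 + 1.0 + lam**-2
    g = lam**2 - lam**-2
    gp = 2.0 * lam + 2.0 * lam**-3
    di1 = 2.0 * lam - 2.0 * lam**-3
    out = 2.0 * gp * dpsi_di1(i1, coeffs) + 2.0 * g * di1 * d2psi_di1_sq(i1, coeffs)
    return out if out.ndim else float(out)


def drucker_stability_check(
    coeffs: YeohCoefficients,
    stretch_range: tuple[float, float],
    n_grid: int = 10_000,
) -> StabilityResult:
    """Material-stability proxy: is the planar-shear stress strictly increasing?

    Drucker stability requires incremental stress to do positive work on
    incremental strain; in the single-parameter planar-shear mode this reduces
    to a positive tangent stiffness. The tangent is evaluated analytically on
    a dense grid over ``stretch_range`` (a closed interval that must contain
    the undeformed stretch 1). Returns the smallest grid stretch at which the
    tangent is non-positive, or ``None`` if the response is stable throughout.
    """
    lo, hi = float(stretch_range[0]), float(stretch_range[1])
    if not (0.0 < lo < hi) or not (lo <= 1.0 <= hi):
        raise ValueError(
            f"stretch_range must satisfy 0 < lo < hi and contain 1, got {stretch_range!r}"
        )
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    lam = np.linspace(lo, hi, n_grid)
    tangent = stress_tangent_planar_shear(lam, coeffs)
    bad = np.flatnonzero(tangent <= 0.0)
    if bad.size:
        return StabilityResult(False, float(lam[bad[0]]))
    return StabilityResult(True, None)
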