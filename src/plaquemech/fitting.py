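"""Yeoh coefficient recovery from planar-shear stress-stretch curves.

Mirrors the experimental workflow: individual sample curves are pooled per
calcification group into a single average curve (a polynomial through the
undeformed point), and the Yeoh coefficients are fitted to that curve by
bounded nonlinear least squares in stress space, with a material-stability
check on the result.

The estimator :class:`YeohCurveFitter` follows the scikit-learn API so fits
compose with pipelines and model selection; :func:`fit_yeoh` is a thin
functional wrapper over it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .constitutive import (
    YeohCoefficients,
    cauchy_stress_planar_shear,
    drucker_stability_check,
)

__all__ = [
    "StressStretchCurve",
    "FitResult",
    "YeohCurveFitter",
    "average_group_curve",
    "fit_yeoh",
    "r_squared",
    "build_material_table",
]

KNOWN_GROUPS = (
    "lightly",
    "moderately",
    "heavily",
    "calcified_aortic",
    "cellular_aortic",
    "hypocellular_aortic",
    "unknown",
)

_STRETCH_START_TOL = 1e-6
_STRESS_START_TOL = 1e-3


@dataclass(frozen=True)
class StressStretchCurve:
    """One sample's planar-shear response: stretch ratios and Cauchy stress (MPa).

    The stretch sequence must be strictly increasing and start at 1 (the
    undeformed state), where the stress must vanish to within 1e-3 MPa.
    """

    stretch: np.ndarray
    stress: np.ndarray
    sample_id: str = ""
    group: str = "unknown"

    def __post_init__(self) -> None:
        stretch = np.asarray(self.stretch, dtype=float)
        stress = np.asarray(self.stress, dtype=float)
        object.__setattr__(self, "stretch", stretch)
        object.__setattr__(self, "stress", stress)
        if stretch.ndim != 1 or stretch.shape != stress.shape:
            raise ValueError("stretch and stress must be 1-D arrays of equal length")
        if stretch.size < 3:
            raise ValueError("a curve needs at least 3 points")
        if np.any(np.diff(stretch) <= 0):
            raise ValueError("stretch must be strictly increasing")
        if abs(stretch[0] - 1.0) > _STRETCH_START_TOL:
            raise ValueError(f"curve must start at stretch 1, got {stretch[0]!r}")
        if abs(stress[0]) > _STRESS_START_TOL:
            raise ValueError(f"stress at stretch 1 must be ~0 MPa, got {stress[0]!r}")
        if self.group not in KNOWN_GROUPS:
            raise ValueError(f"unknown group {self.group!r}")

    def __len__(self) -> int:
        return int(self.stretch.size)


@dataclass(frozen=True)
class FitResult:
    coefficients: YeohCoefficients
    r_squared: float
    stable: bool
    residual_norm: float


def _design_matrix(stretch: np.ndarray) -> np.ndarray:
    """Columns d sigma / d Ci0: the planar-shear stress is linear in the coefficients."""
    lam = np.asarray(stretch, dtype=float)
    x = lam**2 + lam**-2 - 2.0  # I1 - 3
    g = 2.0 * (lam**2 - lam**-2)
    return np.column_stack([g, 2.0 * g * x, 3.0 * g * x**2])


class YeohCurveFitter(RegressorMixin, BaseEstimator):
    """Least-squares fit of the Yeoh planar-shear stress response.

    Minimises the sum of squared stress differences between the model and the
    data, with C10 bounded below (a zero-stiffness material is inadmissible)
    and an optional material-stability requirement on the fitted range.

    Although the stress is linear in (C10, C20, C30), the fit is run as
    bounded nonlinear least squares from multiple seeded starting points: the
    multi-start machinery is what allows stability enforcement by rejection
    and restart without changing the objective.

    Parameters
    ----------
    enforce_stability : bool, default True
        Require the fitted coefficients to give a monotone stress response
        over the data's stretch range. If no candidate satisfies it, the fit
        is repeated with a soft penalty on negative tangent stiffness.
    n_starts : int, default 10
        Number of random restarts (plus one deterministic start at a
        neo-Hookean least-squares guess).
    c10_min : float, default 1e-6
        Lower bound on C10 in MPa.
    random_state : int or None
        Seeds the restart initialisation; the fit is deterministic given it.

    Attributes
    ----------
    coef_ : ndarray of shape (3,)
        Fitted (C10, C20, C30) in MPa.
    coefficients_ : YeohCoefficients
    r_squared_ : float
    stable_ : bool
    residual_norm_ : float
        Euclidean norm of the stress residuals (MPa).
    """

    def __init__(
        self,
        enforce_stability: bool = True,
        n_starts: int = 10,
        c10_min: float = 1e-6,
        random_state: int | None = None,
    ) -> None:
        self.enforce_stability = enforce_stability
        self.n_starts = n_starts
        self.c10_min = c10_min
        self.random_state = random_state

    def _validate_xy(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single stretch column")
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        if X.shape != y.shape or X.ndim != 1:
            raise ValueError("X and y must be matching 1-D sequences")
        if X.size < 3:
            raise ValueError("need at least 3 points to fit 3 coefficients")
        if np.any(X <= 0):
            raise ValueError("stretch values must be positive")
        return X, y

    def fit(self, X, y):
        """Fit to stretch values ``X`` (1 column) and Cauchy stresses ``y`` (MPa)."""
        lam, stress = self._validate_xy(X, y)
        rng = np.random.default_rng(self.random_state)
        lo = np.array([self.c10_min, -np.inf, -np.inf])
        hi = np.array([np.inf, np.inf, np.inf])
        A = _design_matrix(lam)

        def residuals(theta: np.ndarray) -> np.ndarray:
            return A @ theta - stress

        # deterministic start: neo-Hookean slope estimate
        g = A[:, 0]
        denom = float(g @ g)
        c10_guess = max(float(g @ stress) / denom if denom > 0 else 0.1, self.c10_min)
        starts = [np.array([c10_guess, 0.0, 0.0])]
        scale = max(c10_guess, 1e-3)
        for _ in range(max(self.n_starts - 1, 0)):
            starts.append(
                np.array(
                    [
                        max(c10_guess * rng.lognormal(0.0, 1.0), self.c10_min),
                        scale * rng.normal(0.0, 2.0),
                        scale * rng.normal(0.0, 2.0),
                    ]
                )
            )

        lam_range = (min(float(lam.min()), 1.0), max(float(lam.max()), 1.0 + 1e-9))
        best, best_cost = None, np.inf
        best_any, best_any_cost = None, np.inf
        for theta0 in starts:
            sol = least_squares(residuals, theta0, jac=lambda t: A, bounds=(lo, hi))
            if not sol.success:
                continue
            stable = drucker_stability_check(
                _as_coeffs(sol.x, self.c10_min), lam_range
            ).stable
            if sol.cost < best_any_cost:
                best_any, best_any_cost, best_any_stable = sol.x, sol.cost, stable
            if stable and sol.cost < best_cost:
                best, best_cost = sol.x, sol.cost
        if best_any is None:
            raise RuntimeError("Yeoh fit failed to converge from any starting point")

        if self.enforce_stability and best is None:
            best = self._penalised_fit(A, stress, best_any, lam_range)
            best_stable = drucker_stability_check(
                _as_coeffs(best, self.c10_min), lam_range
            ).stable
        elif self.enforce_stability:
            best_stable = True
        else:
            best, best_stable = best_any, best_any_stable

        self.coef_ = np.asarray(best, dtype=float)
        self.coefficients_ = _as_coeffs(self.coef_, self.c10_min)
        self.stable_ = bool(best_stable)
        resid = A @ self.coef_ - stress
        self.residual_norm_ = float(np.linalg.norm(resid))
        ss_tot = float(np.sum((stress - stress.mean()) ** 2))
        self.r_squared_ = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
        self.n_features_in_ = 1
        self.stretch_range_ = lam_range
        return self

    def _penalised_fit(self, A, stress, theta0, lam_range):
        """Fallback: augment the objective with a tangent-positivity penalty."""
        grid = np.linspace(lam_range[0], lam_range[1], 512)
        scale = max(float(np.abs(stress).max()), 1e-6)

        def residuals(theta):
            coeffs = _as_coeffs(theta, self.c10_min)
            from .constitutive import stress_tangent_planar_shear

            tangent = np.asarray(stress_tangent_planar_shear(grid, coeffs))
            penalty = 1e3 * scale * np.minimum(tangent, 0.0)
            return np.concatenate([A @ theta - stress, penalty])

        sol = least_squares(
            residuals,
            theta0,
            bounds=(np.array([self.c10_min, -np.inf, -np.inf]), np.full(3, np.inf)),
        )
        if not sol.success:
            raise RuntimeError("stability-penalised Yeoh fit failed to converge")
        return sol.x

    def predict(self, X):
        """Planar-shear Cauchy stress (MPa) at the given stretch values."""
        check_is_fitted(self)
        lam = np.asarray(X, dtype=float)
        if lam.ndim == 2:
            lam = lam[:, 0]
        return np.asarray(cauchy_stress_planar_shear(lam, self.coefficients_))


def _as_coeffs(theta: np.ndarray, c10_min: float, label: str = "") -> YeohCoefficients:
    return YeohCoefficients(max(float(theta[0]), c10_min), float(theta[1]), float(theta[2]), label)


def average_group_curve(
    curves: list[StressStretchCurve],
    ultimate_stretch: float,
    degree: int = 4,
    n_out: int = 100,
) -> StressStretchCurve:
    """Pool a group's curves into one smooth average curve on [1, ultimate_stretch].

    All (stretch, stress) points are pooled and a single polynomial in
    (stretch - 1) with no constant term — so it passes through the undeformed
    point (1, 0) — is fitted by least squares, then sampled on a uniform grid
    truncated at the group's mean ultimate failure stretch.

    Degree 4 is the default: the Yeoh energy is cubic in (I1 - 3), but the
    planar-shear stress carries the extra geometric factor 2(lam^2 - lam^-2),
    so a cubic in (lam - 1) leaves a visible lack of fit over a typical
    failure-stretch range while a quartic tracks the model to ~1e-5 MPa.
    """
    if not curves:
        raise ValueError("need at least one curve")
    if ultimate_stretch <= 1.0:
        raise ValueError("ultimate_stretch must exceed 1")
    groups = {c.group for c in curves}
    if len(groups) > 1:
        raise ValueError(f"curves must share one group, got {sorted(groups)}")
    group = curves[0].group
    lam = np.concatenate([c.stretch for c in curves])
    sig = np.concatenate([c.stress for c in curves])
    x = lam - 1.0
    V = np.vander(x, degree + 1, increasing=True)[:, 1:]  # drop constant term
    coeffs, *_ = np.linalg.lstsq(V, sig, rcond=None)
    lam_out = np.linspace(1.0, ultimate_stretch, n_out)
    x_out = lam_out - 1.0
    V_out = np.vander(x_out, degree + 1, increasing=True)[:, 1:]
    sig_out = V_out @ coeffs
    sig_out[0] = 0.0
    return StressStretchCurve(lam_out, sig_out, sample_id=f"{group}_average", group=group)


def fit_yeoh(
    curve: StressStretchCurve,
    enforce_stability: bool = True,
    seed: int | None = 0,
) -> FitResult:
    """Fit Yeoh coefficients to one curve; functional wrapper over YeohCurveFitter."""
    est = YeohCurveFitter(enforce_stability=enforce_stability, random_state=seed)
    est.fit(curve.stretch, curve.stress)
    coeffs = YeohCoefficients(
        est.coefficients_.c10,
        est.coefficients_.c20,
        est.coefficients_.c30,
        curve.group,
    )
    return FitResult(
        coefficients=coeffs,
        r_squared=est.r_squared_,
        stable=est.stable_,
        residual_norm=est.residual_norm_,
    )


def r_squared(curve: StressStretchCurve, coeffs: YeohCoefficients) -> float:
    """Coefficient of determination of a Yeoh model against a curve, in stress space."""
    pred = np.asarray(cauchy_stress_planar_shear(curve.stretch, coeffs))
    ss_tot = float(np.sum((curve.stress - curve.stress.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined for a constant stress curve")
    ss_res = float(np.sum((curve.stress - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def build_material_table(
    group_curves: dict[str, StressStretchCurve],
    enforce_stability: bool = True,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Fit each group's averaged curve and tabulate the coefficients.

    Returns a DataFrame indexed by group with columns C10/C20/C30 (MPa),
    r_squared and stable — the package's analogue of a published material
    coefficient table.
    """
    if not group_curves:
        raise ValueError("no group curves supplied")
    rows = []
    for group, curve in group_curves.items():
        res = fit_yeoh(curve, enforce_stability=enforce_stability, seed=seed)
        rows.append(
            {
                "group": group,
                "C10_MPa": res.coefficients.c10,
                "C20_MPa": res.coefficients.c20,
                "C30_MPa": res.coefficients.c30,
                "r_squared": res.r_squared,
                "stable": res.stable,
            }
        )
    return pd.DataFrame(rows).set_index("group")
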