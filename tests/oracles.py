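"""Independent oracles used by the test suite.

Everything here deliberately avoids the code paths it is meant to check:
derivatives come from finite differences of the energy, cylinder stresses
from dense brute-force quadrature of the textbook formula, and the inflation
cross-check from an energy-minimising finite-difference solver with penalty
incompressibility.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def yeoh_energy_direct(i1: float, c10: float, c20: float, c30: float) -> float:
    """Term-by-term polynomial sum (vs the Horner evaluation in the package)."""
    x = i1 - 3.0
    return c10 * x + c20 * x**2 + c30 * x**3


def energy_derivative_fd(strain_energy, i1: float, coeffs, h: float = 1e-6) -> float:
    """Central finite difference of W(I1)."""
    return (strain_energy(i1 + h, coeffs) - strain_energy(i1 - h, coeffs)) / (2 * h)


def planar_shear_stress_fd(strain_energy, first_invariant, lam: float, coeffs,
                           h: float = 1e-7) -> float:
    """sigma = lam * d(W(I1(lam)))/dlam by central differencing along the path."""
    wp = strain_energy(first_invariant(lam + h), coeffs)
    wm = strain_energy(first_invariant(lam - h), coeffs)
    return lam * (wp - wm) / (2 * h)


def stability_scan_brute(stress_fn, coeffs, lo: float, hi: float, n: int = 10_000):
    """Sign scan of numerically differenced stress on a dense grid.

    Returns (stable, first violating stretch or None).
    """
    lam = np.linspace(lo, hi, n)
    sig = np.asarray(stress_fn(lam, coeffs))
    rising = np.diff(sig) > 0
    bad = np.flatnonzero(~rising)
    if bad.size:
        return False, float(lam[bad[0]])
    return True, None


def r_squared_direct(y: np.ndarray, pred: np.ndarray) -> float:
    """Spreadsheet-style 1 - SS_res/SS_tot."""
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot


def cylinder_quadrature_dense(coeffs, Ri: float, Ro: float, ri: float,
                              n: int = 100_000):
    """Brute-force trapezoid evaluation of the incompressible plane-strain
    cylinder stresses on a dense uniform deformed grid.

    Returns (r, sigma_rr, sigma_tt)."""
    a2 = ri**2 - Ri**2
    r_in = np.sqrt(Ri**2 + a2)
    r_out = np.sqrt(Ro**2 + a2)
    r = np.linspace(r_in, r_out, n)
    lam = r / np.sqrt(r**2 - a2)
    x = lam**2 + lam**-2 - 2.0
    dpsi = coeffs.c10 + 2 * coeffs.c20 * x + 3 * coeffs.c30 * x**2
    delta = 2.0 * (lam**2 - lam**-2) * dpsi
    integrand = delta / r
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * np.diff(r))])
    sigma_rr = cum - cum[-1]
    return r, sigma_rr, sigma_rr + delta


def fd_penalty_solver(coeffs, Ri: float, Ro: float, ri: float, n_nodes: int = 500,
                      kappa: float | None = None):
    """Displacement-driven 1D finite-difference solver, penalty incompressibility.

    Minimises the total energy of a compressible Yeoh material augmented with
    a volumetric penalty (kappa/2)(J-1)^2 over nodal deformed radii, with the
    lumen displacement prescribed and the outer surface free. Returns element
    midpoint deformed radii and the hoop Cauchy stress there.
    """
    c10, c20, c30 = coeffs.c10, coeffs.c20, coeffs.c30
    if kappa is None:
        kappa = 1000.0 * c10
    R = np.linspace(Ri, Ro, n_nodes)
    dR = np.diff(R)
    Rm = 0.5 * (R[:-1] + R[1:])
    idx = np.arange(n_nodes - 1)

    def energy_grad(u):
        r = np.concatenate([[ri], u])
        rm = 0.5 * (r[:-1] + r[1:])
        lr = np.diff(r) / dR
        lt = rm / Rm
        x = lr**2 + lt**2 - 2.0
        J = lr * lt
        W = x * (c10 + x * (c20 + x * c30)) + 0.5 * kappa * (J - 1.0) ** 2
        dWdI1 = c10 + 2 * c20 * x + 3 * c30 * x**2
        dWdlr = 2 * lr * dWdI1 + kappa * (J - 1.0) * lt
        dWdlt = 2 * lt * dWdI1 + kappa * (J - 1.0) * lr
        E = float(np.sum(W * Rm * dR))
        g = np.zeros_like(r)
        np.add.at(g, idx, -Rm * dWdlr + 0.5 * dWdlt * dR)
        np.add.at(g, idx + 1, Rm * dWdlr + 0.5 * dWdlt * dR)
        return E, g[1:]

    r0 = np.sqrt(R**2 + ri**2 - Ri**2)
    res = minimize(
        energy_grad, r0[1:], jac=True, method="L-BFGS-B",
        options={"maxiter": 20_000, "ftol": 1e-15, "gtol": 1e-12},
    )
    if not res.success:
        raise RuntimeError(f"FD penalty solver did not converge: {res.message}")
    r = np.concatenate([[ri], res.x])
    rm = 0.5 * (r[:-1] + r[1:])
    lr = np.diff(r) / dR
    lt = rm / Rm
    x = lr**2 + lt**2 - 2.0
    J = lr * lt
    dWdI1 = c10 + 2 * c20 * x + 3 * c30 * x**2
    sigma_tt = 2 * lt**2 * dWdI1 / J + kappa * (J - 1.0)
    return rm, sigma_tt
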