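"""Displacement-driven revascularisation of an idealised concentric stenosis.

The vessel is modelled as two concentric incompressible hyperelastic annuli
in plane strain: an inner plaque layer (from the stenosed lumen to the
healthy-lumen interface) and an outer media/adventitia wall. Revascularisation
is simulated by displacing the luminal surface from the initial-stenosis
radius to the final-stenosis radius.

With plane strain (lam_z = 1) and exact incompressibility, the axisymmetric
motion is fully determined by annular area conservation,

    r(R) = sqrt(R^2 + ri^2 - Ri^2),

so the principal stretches are lam_theta = r/R, lam_r = 1/lam_theta,
lam_z = 1. The radial Cauchy stress follows from the single equilibrium
equation

    d(sigma_rr)/dr = (sigma_tt - sigma_rr) / r,        sigma_rr(r_outer) = 0,

integrated inward from the traction-free outer surface, with the stress
differences given by the Yeoh energy W(I1):

    sigma_tt - sigma_rr = 2 (lam_theta^2 - lam_theta^-2) W'(I1)
    sigma_zz - sigma_rr = 2 (1 - lam_theta^-2) W'(I1)
    I1 = lam_theta^2 + lam_theta^-2 + 1.

This 1D semi-analytic reduction is exact for the concentric quarter-symmetric
geometry; no finite-element mesh is required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from numpy.typing import ArrayLike

from .constitutive import YeohCoefficients, dpsi_di1, drucker_stability_check

__all__ = [
    "VesselGeometry",
    "MaterialAssignment",
    "RadialStressProfile",
    "MaterialComparison",
    "reference_configuration",
    "final_lumen_radius",
    "deformed_radius_map",
    "hoop_stress_difference",
    "solve_revascularisation",
    "equilibrium_residual",
    "stress_at_depth",
    "compare_materials",
]

_STENOSIS_REFERENCES = ("healthy_lumen", "sfa")


@dataclass(frozen=True)
class VesselGeometry:
    """Concentric stenosed femoral artery in the reference configuration.

    Dimensions in mm; stenosis levels as percentage diameter obstruction.
    ``stenosis_reference`` selects whether the percentages refer to the
    healthy lumen diameter or to the outer (SFA) diameter. By default the
    outer wall radius is taken as ``sfa_diameter / 2`` (wall thickness then
    follows from the diameters); set ``honour_wall_thickness`` to build the
    outer radius from the printed wall thickness instead.
    """

    sfa_diameter: float = 6.87
    healthy_lumen_diameter: float = 5.95
    wall_thickness: float = 0.48
    initial_stenosis_pct: float = 90.0
    final_stenosis_pct: float = 10.0
    stenosis_reference: str = "healthy_lumen"
    honour_wall_thickness: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.healthy_lumen_diameter < self.sfa_diameter):
            raise ValueError(
                "require 0 < healthy_lumen_diameter < sfa_diameter, got "
                f"{self.healthy_lumen_diameter} vs {self.sfa_diameter}"
            )
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be positive")
        if not (0 < self.final_stenosis_pct <= self.initial_stenosis_pct < 100):
            raise ValueError(
                "require 0 < final_stenosis_pct <= initial_stenosis_pct < 100"
            )
        if self.stenosis_reference not in _STENOSIS_REFERENCES:
            raise ValueError(
                f"stenosis_reference must be one of {_STENOSIS_REFERENCES}, "
                f"got {self.stenosis_reference!r}"
            )

    @property
    def _reference_diameter(self) -> float:
        if self.stenosis_reference == "healthy_lumen":
            return self.healthy_lumen_diameter
        return self.sfa_diameter


@dataclass(frozen=True)
class MaterialAssignment:
    """Yeoh materials for the plaque layer and the healthy wall layer."""

    plaque: YeohCoefficients
    wall: YeohCoefficients | None

    @property
    def has_wall(self) -> bool:
        return self.wall is not None


@dataclass(frozen=True)
class RadialStressProfile:
    """Stress state along the radial line of interest after revascularisation.

    Arrays run from the (deformed) lumen outward. Stresses in MPa, radii in
    mm. ``sigma_max_principal`` is the pointwise maximum of the radial, hoop
    and axial components (the principal directions in this axisymmetric
    state).
    """

    radius: np.ndarray
    reference_radius: np.ndarray
    depth_from_lumen: np.ndarray
    lam_theta: np.ndarray
    sigma_rr: np.ndarray
    sigma_tt: np.ndarray
    sigma_zz: np.ndarray
    sigma_max_principal: np.ndarray
    geometry: VesselGeometry
    materials: MaterialAssignment
    lumen_radius_initial: float
    lumen_radius_final: float
    interface_radius_reference: float
    outer_radius_reference: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "radius_mm": self.radius,
                "depth_mm": self.depth_from_lumen,
                "hoop_stretch": self.lam_theta,
                "sigma_rr_MPa": self.sigma_rr,
                "sigma_tt_MPa": self.sigma_tt,
                "sigma_zz_MPa": self.sigma_zz,
                "sigma_max_principal_MPa": self.sigma_max_principal,
            }
        )


class MaterialComparison(NamedTuple):
    """Stresses at a fixed depth per plaque material, and pairwise ratios."""

    stresses: pd.DataFrame
    ratios: pd.DataFrame


def reference_configuration(geometry: VesselGeometry) -> tuple[float, float, float]:
    """Reference radii (Ri, Rp, Ro): stenosed lumen, plaque/wall interface, outer wall.

    Ri is the open-lumen radius at the initial stenosis level; Rp is half the
    healthy lumen diameter (where plaque meets wall); Ro is the outer wall
    radius (sfa_diameter/2 by default).
    """
    ri_ref = (1.0 - geometry.initial_stenosis_pct / 100.0) * geometry._reference_diameter / 2.0
    rp = geometry.healthy_lumen_diameter / 2.0
    if geometry.honour_wall_thickness:
        ro = rp + geometry.wall_thickness
    else:
        ro = geometry.sfa_diameter / 2.0
    if not (0 < ri_ref < rp < ro):
        raise ValueError(
            f"reference radii must be strictly ordered, got Ri={ri_ref}, Rp={rp}, Ro={ro}"
        )
    return ri_ref, rp, ro


def final_lumen_radius(geometry: VesselGeometry) -> float:
    """Deformed (post-revascularisation) lumen radius prescribed at the boundary."""
    return (1.0 - geometry.final_stenosis_pct / 100.0) * geometry._reference_diameter / 2.0


def deformed_radius_map(R: ArrayLike, Ri: float, ri: float) -> np.ndarray | float:
    """Deformed radius r = sqrt(R^2 + ri^2 - Ri^2) by annular area conservation."""
    R = np.asarray(R, dtype=float)
    if np.any(R < Ri):
        raise ValueError("reference radius must not lie inside the reference lumen")
    if ri <= 0:
        raise ValueError("deformed lumen radius must be positive")
    out = np.sqrt(R**2 + ri**2 - Ri**2)
    return out if out.ndim else float(out)


def hoop_stress_difference(
    hoop_stretch: ArrayLike, coeffs: YeohCoefficients
) -> np.ndarray | float:
    """sigma_tt - sigma_rr = 2 (lam^2 - lam^-2) W'(I1) with I1 = lam^2 + lam^-2 + 1."""
    lam = np.asarray(hoop_stretch, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("hoop stretch must be positive")
    i1 = lam**2 + lam**-2 + 1.0
    out = 2.0 * (lam**2 - lam**-2) * dpsi_di1(i1, coeffs)
    return out if out.ndim else float(out)


def _layer_dpsi(R: np.ndarray, lam: np.ndarray, Rp: float, mats: MaterialAssignment) -> np.ndarray:
    """W'(I1) at each point, selecting plaque vs wall material by reference radius."""
    i1 = lam**2 + lam**-2 + 1.0
    dp = np.asarray(dpsi_di1(i1, mats.plaque), dtype=float)
    if mats.has_wall:
        in_wall = R > Rp
        if np.any(in_wall):
            dp_wall = np.asarray(dpsi_di1(i1, mats.wall), dtype=float)
            dp = np.where(in_wall, dp_wall, dp)
    return dp


def _reference_grid(Ri: float, Rp: float, Ro: float, n: int, beta: float = 6.0) -> np.ndarray:
    """Grid over [Ri, Ro] geometrically refined toward the lumen, with a node at Rp."""
    t = np.linspace(0.0, 1.0, n)
    R = Ri + (Ro - Ri) * np.expm1(beta * t) / np.expm1(beta)
    R = np.union1d(R, [Rp])
    R[0], R[-1] = Ri, Ro
    return R


def _interval_gauss(r_nodes: np.ndarray, f, order: int = 5) -> np.ndarray:
    """Per-interval Gauss-Legendre integrals of f over consecutive node pairs."""
    xg, wg = leggauss(order)
    a, b = r_nodes[:-1], r_nodes[1:]
    half = 0.5 * (b - a)
    mid = 0.5 * (a + b)
    pts = mid[:, None] + half[:, None] * xg[None, :]
    vals = f(pts.ravel()).reshape(pts.shape)
    return half * (vals @ wg)


def solve_revascularisation(
    geometry: VesselGeometry,
    materials: MaterialAssignment,
    grid_size: int = 4000,
    check_stability: bool = True,
) -> RadialStressProfile:
    """Solve the plane-strain revascularisation problem semi-analytically.

    The kinematics follow from area conservation; the radial stress is
    obtained by per-interval Gauss quadrature of the equilibrium equation,
    accumulated inward from the traction-free outer surface. The grid is
    geometrically refined toward the lumen where hoop-stretch gradients are
    steepest, and always contains a node at the plaque/wall interface so no
    quadrature interval straddles the material discontinuity.

    A warning (not an error) is emitted when a material is unstable over the
    hoop-stretch range the geometry induces: the analysis deliberately
    extrapolates the strain-energy curve beyond each group's tested range,
    since revascularisation drives the tissue far past its failure stretch.
    """
    if grid_size < 100:
        raise ValueError("grid_size must be >= 100")
    Ri, Rp, Ro = reference_configuration(geometry)
    ri = final_lumen_radius(geometry)

    R = _reference_grid(Ri, Rp, Ro, grid_size)
    r = np.asarray(deformed_radius_map(R, Ri, ri))
    lam = r / R

    if check_stability:
        for layer, coeffs, lam_layer in (
            ("plaque", materials.plaque, lam[R <= Rp]),
            ("wall", materials.wall, lam[R >= Rp]),
        ):
            if coeffs is None:
                continue
            lam_max = float(lam_layer.max())
            if lam_max > 1.0:
                result = drucker_stability_check(coeffs, (1.0, lam_max))
                if not result.stable:
                    warnings.warn(
                        f"{layer} material '{coeffs.label}' loses monotone planar-shear "
                        f"response at stretch {result.first_violation:.4g} "
                        f"(induced range up to {lam_max:.4g}); proceeding with the "
                        "extrapolated strain-energy curve",
                        RuntimeWarning,
                        stacklevel=2,
                    )

    if not materials.has_wall:
        keep = R <= Rp
        R, r, lam = R[keep], r[keep], lam[keep]
        Ro_eff = Rp
    else:
        Ro_eff = Ro

    a2 = ri**2 - Ri**2

    def integrand(r_pts: np.ndarray) -> np.ndarray:
        R_pts = np.sqrt(np.maximum(r_pts**2 - a2, 0.0))
        lam_pts = r_pts / R_pts
        dp = _layer_dpsi(R_pts, lam_pts, Rp, materials)
        return 2.0 * (lam_pts**2 - lam_pts**-2) * dp / r_pts

    seg = _interval_gauss(r, integrand)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    # sigma_rr(r_k) = -int_{r_k}^{r_outer} (sigma_tt - sigma_rr)/r dr
    sigma_rr = cum - cum[-1]

    dp_nodes = _layer_dpsi(R, lam, Rp, materials)
    delta_tt = 2.0 * (lam**2 - lam**-2) * dp_nodes
    delta_zz = 2.0 * (1.0 - lam**-2) * dp_nodes
    sigma_tt = sigma_rr + delta_tt
    sigma_zz = sigma_rr + delta_zz
    sigma_max = np.maximum(np.maximum(sigma_rr, sigma_tt), sigma_zz)

    return RadialStressProfile(
        radius=r,
        reference_radius=R,
        depth_from_lumen=r - r[0],
        lam_theta=lam,
        sigma_rr=sigma_rr,
        sigma_tt=sigma_tt,
        sigma_zz=sigma_zz,
        sigma_max_principal=sigma_max,
        geometry=geometry,
        materials=materials,
        lumen_radius_initial=Ri,
        lumen_radius_final=ri,
        interface_radius_reference=Rp,
        outer_radius_reference=Ro_eff,
    )


def equilibrium_residual(profile: RadialStressProfile, order: int = 15) -> float:
    """Max absolute residual (MPa) of the radial equilibrium ODE on the grid.

    Re-evaluates each interval integral of (sigma_tt - sigma_rr)/r with a
    higher-order Gauss rule than the solver used and compares it against the
    stored sigma_rr increments; also checks the traction-free outer boundary.
    """
    mats = profile.materials
    Ri = profile.lumen_radius_initial
    ri = profile.lumen_radius_final
    Rp = profile.interface_radius_reference
    a2 = ri**2 - Ri**2

    def integrand(r_pts: np.ndarray) -> np.ndarray:
        R_pts = np.sqrt(np.maximum(r_pts**2 - a2, 0.0))
        lam_pts = r_pts / R_pts
        dp = _layer_dpsi(R_pts, lam_pts, Rp, mats)
        return 2.0 * (lam_pts**2 - lam_pts**-2) * dp / r_pts

    seg = _interval_gauss(profile.radius, integrand, order=order)
    increments = np.diff(profile.sigma_rr)
    res = float(np.max(np.abs(increments - seg))) if seg.size else 0.0
    return max(res, float(abs(profile.sigma_rr[-1])))


def stress_at_depth(
    profile: RadialStressProfile,
    depth: float,
    convention: str = "deformed",
    field: str = "sigma_max_principal",
) -> float:
    """Interpolate a profile field at a depth (mm) from the lumen.

    ``convention='deformed'`` measures the depth along the deformed radius
    from the revascularised lumen surface; ``'reference'`` measures it in the
    reference configuration from the stenosed lumen and maps the point
    forward through the deformation.
    """
    if convention not in ("deformed", "reference"):
        raise ValueError(f"convention must be 'deformed' or 'reference', got {convention!r}")
    if depth < 0:
        raise ValueError("depth must be non-negative")
    if convention == "deformed":
        r_query = profile.radius[0] + depth
    else:
        R_query = profile.reference_radius[0] + depth
        if R_query > profile.reference_radius[-1]:
            raise ValueError("depth lies outside the vessel wall")
        r_query = float(
            deformed_radius_map(R_query, profile.lumen_radius_initial, profile.lumen_radius_final)
        )
    if r_query > profile.radius[-1] + 1e-12:
        raise ValueError("depth lies outside the vessel wall")
    values = getattr(profile, field)
    return float(np.interp(r_query, profile.radius, values))


def compare_materials(
    geometry: VesselGeometry,
    plaque_materials: Mapping[str, YeohCoefficients],
    wall: YeohCoefficients | None,
    depth: float = 0.8,
    convention: str = "deformed",
    grid_size: int = 4000,
    check_stability: bool = False,
) -> MaterialComparison:
    """Maximum principal stress at a fixed depth for each plaque material.

    Runs one revascularisation per plaque material (all sharing the same wall
    model), extracts the maximum principal stress at ``depth``, and forms the
    full matrix of pairwise fold changes, oriented so that
    ``ratios.loc[a, b]`` is stress(a) / stress(b).
    """
    if len(plaque_materials) < 2:
        raise ValueError("need at least two plaque materials to compare")
    stresses = {}
    for label, coeffs in plaque_materials.items():
        profile = solve_revascularisation(
            geometry,
            MaterialAssignment(plaque=coeffs, wall=wall),
            grid_size=grid_size,
            check_stability=check_stability,
        )
        stresses[label] = stress_at_depth(profile, depth, convention)
    stress_df = pd.DataFrame(
        {
            "group": list(stresses),
            "sigma_max_principal_MPa": list(stresses.values()),
        }
    ).set_index("group")
    vals = stress_df["sigma_max_principal_MPa"]
    ratio_df = pd.DataFrame(
        np.asarray(vals)[:, None] / np.asarray(vals)[None, :],
        index=vals.index,
        columns=vals.index,
    )
    return MaterialComparison(stresses=stress_df, ratios=ratio_df)
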