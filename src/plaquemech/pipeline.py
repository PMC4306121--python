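"""End-to-end study orchestration: fit, solve, compare, assess failure.

A single validated configuration drives the whole analysis: build (or fit)
the six plaque material models, revascularise the idealised stenosis once per
plaque material with a shared wall model, extract the maximum principal
stress at the reporting depth, form fold changes between materials, assess
each result against its group's ultimate failure criterion, and sweep the
undocumented modelling choices (wall stiffness, stenosis-percentage
reference, depth convention) in a sensitivity appendix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import materials as matlib
from .constitutive import YeohCoefficients
from .failure import failure_report
from .fitting import StressStretchCurve, average_group_curve, build_material_table
from .inflation import (
    MaterialAssignment,
    VesselGeometry,
    compare_materials,
    solve_revascularisation,
)

__all__ = [
    "GeometryConfig",
    "WallConfig",
    "StudyConfig",
    "StudyReport",
    "validate_config",
    "run_study",
]

HEADLINE_PAIR = ("calcified_aortic", "heavily")
SENSITIVITY_WALL_C10 = (0.01, 0.05, 0.2)


class GeometryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    sfa_diameter: float = 6.87
    healthy_lumen_diameter: float = 5.95
    wall_thickness: float = 0.48
    initial_stenosis_pct: float = 90.0
    final_stenosis_pct: float = 10.0
    stenosis_reference: Literal["healthy_lumen", "sfa"] = "healthy_lumen"
    honour_wall_thickness: bool = False

    @model_validator(mode="after")
    def _check(self):
        VesselGeometry(**self.model_dump())  # reuse the dataclass invariants
        return self

    def build(self) -> VesselGeometry:
        return VesselGeometry(**self.model_dump())


class WallConfig(BaseModel):
    """Healthy wall material: explicit Yeoh coefficients, or one of the
    special modes 'plaque' (wall shares the plaque model) / 'none' (no wall
    layer; the plaque outer surface is traction-free)."""

    model_config = ConfigDict(extra="forbid")

    mode: Literal["coefficients", "plaque", "none"] = "coefficients"
    c10: float = 0.05
    c20: float = 0.0
    c30: float = 0.0

    def resolve(self, plaque: YeohCoefficients) -> YeohCoefficients | None:
        if self.mode == "none":
            return None
        if self.mode == "plaque":
            return plaque
        return YeohCoefficients(self.c10, self.c20, self.c30, "wall")


class StudyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    depth_mm: float = 0.8
    depth_convention: Literal["deformed", "reference"] = "deformed"
    wall: WallConfig = Field(default_factory=WallConfig)
    material_source: Literal["builtin", "fitted"] = "builtin"
    curve_files: dict[str, list[str]] = Field(default_factory=dict)
    output_dir: str = "study_output"
    grid_size: int = Field(default=4000, ge=100)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.depth_mm <= 0:
            raise ValueError("depth_mm must be positive")
        geom = self.geometry.build()
        from .inflation import reference_configuration

        ri, rp, ro = reference_configuration(geom)
        # static sanity bound; the exact (deformed) check happens at solve time
        if self.depth_mm >= ro - ri:
            raise ValueError("depth_mm lies outside the vessel wall")
        if self.material_source == "fitted":
            if not self.curve_files:
                raise ValueError("material_source='fitted' requires curve_files")
            missing = [
                p for paths in self.curve_files.values() for p in paths if not Path(p).exists()
            ]
            if missing:
                raise ValueError(f"missing input file(s): {missing}")
        return self


@dataclass
class StudyReport:
    coefficient_table: pd.DataFrame
    stresses: pd.DataFrame
    fold_changes: pd.DataFrame
    failure: pd.DataFrame
    sensitivity: pd.DataFrame
    headline_ratio: float
    output_dir: Path | None


def validate_config(path: str | Path) -> StudyConfig:
    """Load and validate a YAML/JSON study configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return StudyConfig.model_validate(raw)


def _read_curve(path: str, group: str) -> StressStretchCurve:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (stretch, stress_MPa)")
    return StressStretchCurve(
        df.iloc[:, 0].to_numpy(float),
        df.iloc[:, 1].to_numpy(float),
        sample_id=Path(path).stem,
        group=group,
    )


def _material_table(config: StudyConfig) -> tuple[pd.DataFrame, dict[str, YeohCoefficients]]:
    if config.material_source == "builtin":
        mats = dict(matlib.PLAQUE_MATERIALS)
        table = pd.DataFrame(
            {
                "group": list(mats),
                "C10_MPa": [m.c10 for m in mats.values()],
                "C20_MPa": [m.c20 for m in mats.values()],
                "C30_MPa": [m.c30 for m in mats.values()],
            }
        ).set_index("group")
        return table, mats
    group_curves = {}
    for group, paths in config.curve_files.items():
        curves = [_read_curve(p, group) for p in paths]
        ultimate = matlib.FAILURE_CRITERIA[group].ultimate_stretch_mean
        group_curves[group] = average_group_curve(curves, ultimate)
    table = build_material_table(group_curves, seed=config.seed)
    mats = {
        g: YeohCoefficients(row.C10_MPa, row.C20_MPa, row.C30_MPa, g)
        for g, row in table.iterrows()
    }
    return table, mats


def _headline_ratio(
    geometry: VesselGeometry,
    mats: dict[str, YeohCoefficients],
    wall: YeohCoefficients | None,
    depth: float,
    convention: str,
    grid_size: int,
) -> float:
    comparison = compare_materials(
        geometry,
        {k: mats[k] for k in HEADLINE_PAIR},
        wall,
        depth=depth,
        convention=convention,
        grid_size=grid_size,
    )
    return float(comparison.ratios.loc[HEADLINE_PAIR[0], HEADLINE_PAIR[1]])


def _sensitivity_grid(
    config: StudyConfig, mats: dict[str, YeohCoefficients]
) -> pd.DataFrame:
    rows = []
    for reference in ("healthy_lumen", "sfa"):
        geom = VesselGeometry(
            **{**config.geometry.model_dump(), "stenosis_reference": reference}
        )
        for convention in ("deformed", "reference"):
            for c10 in SENSITIVITY_WALL_C10:
                wall = YeohCoefficients(c10, 0.0, 0.0, "wall")
                ratio = _headline_ratio(
                    geom, mats, wall, config.depth_mm, convention, config.grid_size
                )
                rows.append(
                    {
                        "stenosis_reference": reference,
                        "depth_convention": convention,
                        "wall_c10_MPa": c10,
                        "headline_ratio": ratio,
                    }
                )
    return pd.DataFrame(rows)


def run_study(config: StudyConfig, write: bool = True) -> StudyReport:
    """Execute the full analysis described by ``config``.

    Returns the in-memory report and, unless ``write=False``, writes the
    coefficient table, per-material stress profiles, fold-change table,
    failure report, sensitivity appendix and a run manifest under
    ``config.output_dir``.
    """
    geometry = config.geometry.build()
    table, mats = _material_table(config)

    profiles = {}
    for group, coeffs in mats.items():
        assignment = MaterialAssignment(plaque=coeffs, wall=config.wall.resolve(coeffs))
        profiles[group] = solve_revascularisation(
            geometry, assignment, grid_size=config.grid_size, check_stability=False
        )

    # stresses at the reporting depth come from the profiles already solved
    # (covers all wall modes, including wall-follows-plaque)
    from .inflation import stress_at_depth

    vals = {
        g: stress_at_depth(p, config.depth_mm, config.depth_convention)
        for g, p in profiles.items()
    }
    stresses = pd.DataFrame(
        {"group": list(vals), "sigma_max_principal_MPa": list(vals.values())}
    ).set_index("group")
    arr = stresses["sigma_max_principal_MPa"].to_numpy()
    ratios = pd.DataFrame(
        arr[:, None] / arr[None, :], index=stresses.index, columns=stresses.index
    )

    criteria = {g: matlib.FAILURE_CRITERIA[g] for g in mats if g in matlib.FAILURE_CRITERIA}
    fail = failure_report(
        {g: profiles[g] for g in criteria},
        criteria,
        depth=config.depth_mm,
        convention=config.depth_convention,
    )

    headline = (
        float(ratios.loc[HEADLINE_PAIR[0], HEADLINE_PAIR[1]])
        if all(k in ratios.index for k in HEADLINE_PAIR)
        else float("nan")
    )
    sensitivity = _sensitivity_grid(config, mats)

    out_dir: Path | None = None
    if write:
        out_dir = Path(config.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "materials.csv")
        for group, profile in profiles.items():
            profile.to_frame().to_csv(out_dir / f"profile_{group}.csv", index=False)
        stresses.to_csv(out_dir / "stress_at_depth.csv")
        ratios.to_csv(out_dir / "fold_changes.csv")
        fail.to_csv(out_dir / "failure_report.csv", index=False)
        sensitivity.to_csv(out_dir / "sensitivity.csv", index=False)
        try:
            pkg_version = version("plaquemech")
        except PackageNotFoundError:
            pkg_version = "unknown"
        manifest = {
            "package_version": pkg_version,
            "config": config.model_dump(),
            "headline_pair": list(HEADLINE_PAIR),
            "headline_ratio": headline,
            "failure_summary": {
                k: list(v) for k, v in fail.attrs.get("summary", {}).items()
            },
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    return StudyReport(
        coefficient_table=table,
        stresses=stresses,
        fold_changes=ratios,
        failure=fail,
        sensitivity=sensitivity,
        headline_ratio=headline,
        output_dir=out_dir,
    )
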