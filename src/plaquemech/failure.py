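"""Ultimate-failure assessment of computed plaque stress/stretch states.

Each material group carries the mean (and, where reported, standard
deviation) of the stretch ratio and Cauchy stress at ultimate mechanically
induced failure. A computed state is flagged as failed when it strictly
exceeds the group mean of the selected quantity; exact equality is treated as
not failed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

import pandas as pd

if TYPE_CHECKING:
    from .inflation import RadialStressProfile

__all__ = ["FailureCriterion", "FailureAssessment", "exceeds_failure", "failure_report"]


@dataclass(frozen=True)
class FailureCriterion:
    """Group-mean ultimate failure point: stretch ratio and Cauchy stress (MPa)."""

    ultimate_stretch_mean: float
    ultimate_stretch_sd: float | None
    ultimate_stress_mean: float
    ultimate_stress_sd: float | None
    group: str = ""

    def __post_init__(self) -> None:
        if not (self.ultimate_stretch_mean > 1.0):
            raise ValueError("ultimate stretch mean must exceed 1")
        if not (self.ultimate_stress_mean > 0.0):
            raise ValueError("ultimate stress mean must be positive")


@dataclass(frozen=True)
class FailureAssessment:
    failed: bool
    stress_margin: float
    stretch_margin: float


def exceeds_failure(
    stress: float,
    stretch: float,
    criterion: FailureCriterion,
    mode: str = "stress",
) -> FailureAssessment:
    """Compare a (stress, stretch) state against a group failure criterion.

    Parameters
    ----------
    stress, stretch
        Maximum principal Cauchy stress (MPa) and hoop stretch at the point
        of interest; both must be non-negative (stretch may be 0 only as a
        placeholder when mode='stress').
    mode
        'stress', 'stretch', or 'either'. Failure requires strict exceedance
        of the criterion mean; margins are value minus mean.
    """
    if not (math.isfinite(stress) and math.isfinite(stretch)):
        raise ValueError("stress and stretch must be finite")
    if stress < 0 or stretch < 0:
        raise ValueError("stress and stretch must be non-negative")
    if mode not in ("stress", "stretch", "either"):
        raise ValueError(f"mode must be 'stress', 'stretch' or 'either', got {mode!r}")
    stress_margin = stress - criterion.ultimate_stress_mean
    stretch_margin = stretch - criterion.ultimate_stretch_mean
    stress_failed = stress_margin > 0
    stretch_failed = stretch_margin > 0
    failed = {
        "stress": stress_failed,
        "stretch": stretch_failed,
        "either": stress_failed or stretch_failed,
    }[mode]
    return FailureAssessment(failed, stress_margin, stretch_margin)


def failure_report(
    profiles: Mapping[str, "RadialStressProfile"],
    criteria: Mapping[str, FailureCriterion],
    depth: float = 0.8,
    convention: str = "deformed",
    mode: str = "stress",
) -> pd.DataFrame:
    """Tabulate failure outcomes at a fixed depth for a set of simulations.

    One row per plaque material: maximum principal stress at ``depth`` mm from
    the lumen, hoop stretch there, the criterion mean, the failed flag, and
    the tissue origin. Summary counts per origin are attached as
    ``df.attrs['summary']`` (a mapping origin -> (n_failed, n_total)).
    """
    from .inflation import stress_at_depth
    from .materials import tissue_origin

    missing = set(profiles) - set(criteria)
    if missing:
        raise KeyError(f"no failure criterion for material(s): {sorted(missing)}")
    rows = []
    for group, profile in profiles.items():
        crit = criteria[group]
        stress = stress_at_depth(profile, depth, convention)
        stretch = stress_at_depth(profile, depth, convention, field="lam_theta")
        assessment = exceeds_failure(stress, stretch, crit, mode=mode)
        rows.append(
            {
                "group": group,
                "origin": tissue_origin(group),
                "stress_MPa": stress,
                "hoop_stretch": stretch,
                "ultimate_stress_MPa": crit.ultimate_stress_mean,
                "ultimate_stretch": crit.ultimate_stretch_mean,
                "failed": assessment.failed,
                "stress_margin_MPa": assessment.stress_margin,
            }
        )
    df = pd.DataFrame(rows)
    summary = {
        origin: (int(sub["failed"].sum()), len(sub))
        for origin, sub in df.groupby("origin")
    }
    df.attrs["summary"] = summary
    return df
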