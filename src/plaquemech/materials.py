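"""Published material library: Yeoh coefficients and ultimate failure points.

Six plaque material models are shipped with the package. Three were derived
from planar-shear testing of human femoral plaque samples graded by FTIR
calcification level (lightly / moderately / heavily calcified), and three from
the classical aortic plaque data set widely reused in the literature
(calcified / cellular / hypocellular). Coefficients are in MPa.

Each material carries the group-mean ultimate mechanically induced failure
point (stretch ratio and Cauchy stress) used by the failure assessment. The
hypocellular aortic group was reported without standard deviations.
"""

from __future__ import annotations

from .constitutive import YeohCoefficients
from .failure import FailureCriterion

__all__ = [
    "FEMORAL_GROUPS",
    "AORTIC_GROUPS",
    "PLAQUE_MATERIALS",
    "FAILURE_CRITERIA",
    "DEFAULT_WALL",
    "tissue_origin",
]

FEMORAL_GROUPS = ("lightly", "moderately", "heavily")
AORTIC_GROUPS = ("calcified_aortic", "cellular_aortic", "hypocellular_aortic")

PLAQUE_MATERIALS: dict[str, YeohCoefficients] = {
    "lightly": YeohCoefficients(4.98e-02, -6.19e-03, 8.98e-04, "lightly"),
    "moderately": YeohCoefficients(1.35e-01, -2.84e-02, 4.90e-03, "moderately"),
    "heavily": YeohCoefficients(4.62e-02, -1.47e-02, 4.95e-03, "heavily"),
    "calcified_aortic": YeohCoefficients(1.41e-03, 4.73e00, 8.51e-01, "calcified_aortic"),
    "cellular_aortic": YeohCoefficients(4.84e-03, 3.59e-01, 6.08e-01, "cellular_aortic"),
    "hypocellular_aortic": YeohCoefficients(2.20e-01, 5.09e-01, 6.19e-01, "hypocellular_aortic"),
}

FAILURE_CRITERIA: dict[str, FailureCriterion] = {
    "lightly": FailureCriterion(2.16, 0.09, 0.30, 0.01, "lightly"),
    "moderately": FailureCriterion(1.75, 0.19, 0.43, 0.11, "moderately"),
    "heavily": FailureCriterion(1.55, 0.21, 0.16, 0.04, "heavily"),
    "calcified_aortic": FailureCriterion(1.19, 0.04, 0.52, 0.34, "calcified_aortic"),
    "cellular_aortic": FailureCriterion(1.42, 0.14, 0.74, 0.27, "cellular_aortic"),
    "hypocellular_aortic": FailureCriterion(1.23, None, 0.67, None, "hypocellular_aortic"),
}

# Healthy media/adventitia model. The source study never specifies the wall
# material, so a soft neo-Hookean wall (mu = 2*C10 = 0.1 MPa) is the default;
# the pipeline reports sensitivity of the headline ratio to this choice.
DEFAULT_WALL = YeohCoefficients(0.05, 0.0, 0.0, "wall_neo_hookean")


def tissue_origin(group: str) -> str:
    """'femoral', 'aortic', or 'other' for a material group label."""
    if group in FEMORAL_GROUPS:
        return "femoral"
    if group in AORTIC_GROUPS:
        return "aortic"
    return "other"
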