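import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import plaquemech as pm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def femoral_heavy():
    return pm.PLAQUE_MATERIALS["heavily"]


@pytest.fixture(scope="session")
def aortic_calcified():
    return pm.PLAQUE_MATERIALS["calcified_aortic"]


@pytest.fixture(scope="session")
def neo_hookean():
    return pm.YeohCoefficients(1.0, 0.0, 0.0, "neo")


@pytest.fixture(scope="session")
def default_geometry():
    return pm.VesselGeometry()


@pytest.fixture()
def noiseless_curve(femoral_heavy):
    lam = np.linspace(1.0, 1.55, 50)
    stress = np.asarray(pm.cauchy_stress_planar_shear(lam, femoral_heavy))
    return pm.StressStretchCurve(lam, stress, sample_id="synthetic", group="heavily")
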