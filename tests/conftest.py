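"""Shared fixtures: reference parameter sets and randomized valid materials."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from porelax.constitutive import (
    ConstitutiveError,
    EngineeringConstants,
    ScaffoldParameters,
    stiffness_from_engineering,
)

settings.register_profile(
    "porelax",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("porelax")


#: estimated scaffold parameter sets used throughout as ground truth
REFERENCE = {
    0.5: dict(E1=8.49, E3=19.19, nu21=0.75, nu31=0.24, tg=40.62),
    0.7: dict(E1=5.61, E3=11.97, nu21=0.82, nu31=0.24, tg=17.58),
}


@pytest.fixture(params=[0.5, 0.7], ids=["phi50", "phi70"])
def reference_set(request):
    """One reference parameter set with its porosity label."""
    d = dict(REFERENCE[request.param])
    d["porosity"] = request.param
    return d


@pytest.fixture
def reference_scaffold(reference_set):
    return ScaffoldParameters(**{k: v for k, v in reference_set.items()})


def random_engineering_constants(rng, n):
    """Draw n valid transversely isotropic parameter sets."""
    out = []
    while len(out) < n:
        E1 = rng.uniform(1.0, 30.0)
        E3 = rng.uniform(2.0, 40.0)
        nu31 = rng.uniform(0.0, 0.45)
        nu_max = 1.0 - 2.0 * nu31**2 * E1 / E3
        if nu_max < 0.1:
            continue
        nu21 = rng.uniform(0.0, 0.9 * nu_max)
        try:
            ec = EngineeringConstants(E1=E1, E3=E3, nu21=nu21, nu31=nu31)
            stiffness_from_engineering(ec)  # must be admissible
        except ConstitutiveError:
            continue
        out.append(ec)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240317)
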