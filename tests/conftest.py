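from types import SimpleNamespace

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

import edtox
from edtox.records import Arm


@pytest.fixture(scope="session")
def pilot_run():
    """One full pilot-profile pipeline run, shared across the session."""
    result = edtox.pilot2019(seed=1)
    candidates = edtox.search_cohort(result.cohort)
    traditional = edtox.search_cohort(result.cohort, arms=[Arm.REASON, Arm.LAB, Arm.ICD])
    fws_only = edtox.search_cohort(result.cohort, arms=[Arm.FWS])
    cases = edtox.adjudicate_cohort(result.cohort, candidates, result.evidence)
    return SimpleNamespace(
        result=result,
        cohort=result.cohort,
        candidates=candidates,
        traditional=traditional,
        fws=fws_only,
        cases=cases,
        confirmed=[c for c in cases if c.confirmed],
    )


@pytest.fixture()
def tiny_cohort():
    """Small parametric cohort for matcher-oracle and io round-trip tests."""
    params = edtox.GeneratorParams(n_patients=40, seed=11,
                                   intoxication_prevalence=0.2)
    return edtox.generate_cohort(params)
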