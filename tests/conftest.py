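"""Shared fixtures: base-case parameters and the calibrated synthetic life table.

Calibration and cohort runs are deterministic, so expensive objects are built
once per session.
"""

import warnings

import pytest
from hypothesis import HealthCheck, settings

import afscreen as afs
from afscreen.lifetables import calibrate_median_survival, gompertz_life_table

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return afs.default_parameters()


@pytest.fixture(scope="session")
def gompertz(params):
    return calibrate_median_survival(start_age=55, target_median=10.0, params=params)


@pytest.fixture(scope="session")
def lifetable(gompertz):
    return gompertz_life_table(gompertz, 55, 110)


@pytest.fixture(scope="session")
def lifetables_by_age(gompertz):
    return {age: gompertz_life_table(gompertz, age, 110) for age in (45, 55, 65)}


@pytest.fixture(scope="session")
def base_eval(params, lifetable):
    """Base-case evaluation, 100% NOAC."""
    return afs.evaluate_screening(params, lifetable)


@pytest.fixture(scope="session")
def eval_by_mix(params, lifetable):
    out = {}
    for label, frac in (("noac", 1.0), ("mix5050", 0.5), ("warfarin", 0.0)):
        out[label] = afs.evaluate_screening(params, lifetable,
                                            mix=afs.TreatmentMix(frac_noac=frac))
    return out


@pytest.fixture(autouse=True)
def _no_truncation_noise():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="cohort not extinct")
        yield
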