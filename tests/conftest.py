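"""Shared fixtures.

Expensive artifacts (stressed time course, phase portrait, variant
comparison) are session-scoped so the unit suite and the acceptance
checks reuse one computation.
"""

import numpy as np
import pytest

import triosc

STRESS = dict(triosc.STRESS_SCENARIO)
RAPA_TOTAL = triosc.RAPAMYCIN_MTORC1_TOTAL


@pytest.fixture(scope="session")
def ref_model():
    """Reference model, variant A, no stress."""
    return triosc.reference_model("A")


@pytest.fixture(scope="session")
def stressed_model():
    return triosc.reference_model("A", **STRESS)


@pytest.fixture(scope="session")
def rapa_model():
    return triosc.reference_model("A", mtorc1_total=RAPA_TOTAL)


@pytest.fixture(scope="session")
def rest_fp(ref_model):
    """Unique stable resting state of the unstressed reference model."""
    return triosc.no_stress_fixed_point(ref_model)


@pytest.fixture(scope="session")
def tc_stressed(stressed_model, rest_fp):
    """Stress applied at t=0 from the resting state, 400 time units."""
    return triosc.integrate(stressed_model, t_end=400.0, x0=rest_fp.state)


@pytest.fixture(scope="session")
def tc_rapa(rapa_model, rest_fp):
    x0 = np.minimum(rest_fp.state, rapa_model.totals)
    return triosc.integrate(rapa_model, t_end=400.0, x0=x0)


@pytest.fixture(scope="session")
def stressed_fixed_points(stressed_model):
    return triosc.steady_state(stressed_model, n_starts=64, seed=0)


@pytest.fixture(scope="session")
def reduced_stressed(stressed_model):
    return triosc.qss_reduce(stressed_model)


@pytest.fixture(scope="session")
def portrait_stressed(stressed_model):
    return triosc.portrait(stressed_model, t_end=300.0, seed=0)


@pytest.fixture(scope="session")
def comparison(stressed_model):
    return triosc.compare_variants(stressed_model.parameters, t_end=400.0)
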