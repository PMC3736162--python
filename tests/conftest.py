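import numpy as np
import pytest

import mdstiming as m
from mdstiming.likelihood import FittedModel
from mdstiming.model_core import Scheme, StateSpace, TransitionStructure


@pytest.fixture(scope="session")
def ipss_params():
    return m.default_fixture_parameters("IPSS")


@pytest.fixture(scope="session")
def wpss_params():
    return m.default_fixture_parameters("WPSS")


@pytest.fixture(scope="session")
def truth_fitted(ipss_params):
    """The IPSS fixture truth wrapped as a fitted model (no estimation)."""
    p = ipss_params
    return FittedModel.from_parameters(p.space, p.structure, p.q, p.effects)


@pytest.fixture(scope="session")
def truth_fitted_wpss(wpss_params):
    p = wpss_params
    return FittedModel.from_parameters(p.space, p.structure, p.q, p.effects)


@pytest.fixture(scope="session")
def small_cohorts(ipss_params):
    """A small paired-cohort dataset for fast fitting tests."""
    nh = m.generate_natural_history_cohort(ipss_params, n=150, seed=5)
    tx = m.generate_transplant_cohort(ipss_params, n=100, seed=6)
    return [nh, tx]


@pytest.fixture(scope="session")
def small_fit(ipss_params, small_cohorts):
    return m.fit_model(
        small_cohorts,
        ipss_params.space,
        ipss_params.structure,
        options={"covariance": False},
    )


# --- tiny ad-hoc state spaces for closed-form checks -----------------------

@pytest.fixture(scope="session")
def two_state():
    """Alive -> Death at rate 0.5/yr."""
    space = StateSpace(
        scheme=Scheme.IPSS,
        states=("AML", "Death"),
        aml_index=0,
        death_index=1,
        transplantable=frozenset({0}),
    )
    structure = TransitionStructure(allowed=frozenset({(0, 1)}))
    q = np.array([[-0.5, 0.5], [0.0, 0.0]])
    return space, structure, q


@pytest.fixture(scope="session")
def three_state_chain():
    """A -> B at 1.0/yr, A -> Death at 0.3/yr, B -> Death at 2.0/yr."""
    space = StateSpace(
        scheme=Scheme.IPSS,
        states=("A", "B", "Death"),
        aml_index=1,
        death_index=2,
        transplantable=frozenset({0, 1}),
    )
    structure = TransitionStructure(allowed=frozenset({(0, 1), (0, 2), (1, 2)}))
    q = np.array([[-1.3, 1.0, 0.3], [0.0, -2.0, 2.0], [0.0, 0.0, 0.0]])
    return space, structure, q
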