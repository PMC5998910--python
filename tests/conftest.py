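"""Shared fixtures: built-in nets, tiny closed-form nets, and one shared
fuzzy heat shock run (session-scoped: it is the expensive piece reused by
the band-range and trace-query tests)."""

import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from fcpn import (
    AlphaLevelGrid,
    Arc,
    FuzzyContinuousPetriNet,
    Place,
    RateSpec,
    SamplingPlan,
    SolverSettings,
    Transition,
    TriangularFuzzyNumber,
    decay_dimerization,
    heat_shock_response,
    run_fuzzy_simulation,
)
from fcpn import HEAT_SHOCK_HORIZON


def make_one_species_decay(theta, x0=1.0):
    """dx/dt = -theta x with a crisp or fuzzy rate constant."""
    return FuzzyContinuousPetriNet(
        places=[Place("X", x0)],
        transitions=[Transition("deg", RateSpec("theta"))],
        arcs=[Arc("X", "deg")],
        parameters={"theta": theta},
        name="one_species_decay",
    )


@pytest.fixture
def decay_net():
    return decay_dimerization()


@pytest.fixture
def heat_net():
    return heat_shock_response()


@pytest.fixture
def fuzzy_decay_one():
    return make_one_species_decay(TriangularFuzzyNumber(0.1, 0.2, 0.3))


@pytest.fixture(scope="session")
def heat_fuzzy_result():
    """Fuzzy heat shock run: k8 and T fuzzy, four alpha levels (0, 0.4,
    0.7, 1), efficient sampling with K=3, over the 4-hour study horizon."""
    net = heat_shock_response(fuzzy=True)
    plan = SamplingPlan(
        AlphaLevelGrid.from_levels([0.0, 0.4, 0.7, 1.0]),
        samples_per_cut=3,
        strategy="efficient",
    )
    settings = SolverSettings(t_end=HEAT_SHOCK_HORIZON, n_points=721)
    return run_fuzzy_simulation(net, plan, settings)
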