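import logging

import pytest

from gyflux.model import MetabolicModel, Metabolite, Reaction
from gyflux.synth import (
    ConditionSpec,
    DEFAULT_INITIAL_CONC,
    default_conditions,
    simulate_study,
)

logging.getLogger("gyflux").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def toy_model():
    from gyflux.toynet import toy_cho_network

    return toy_cho_network()


@pytest.fixture(scope="session")
def gy_model(toy_model):
    from gyflux.model import augment_with_gy

    return augment_with_gy(toy_model)


@pytest.fixture
def noiseless_condition():
    """One dose condition with no measurement noise or biological scatter."""
    return ConditionSpec(
        "GY0.5x", 0.5, noise_cv=0.0, n_replicates=1, rate_heterogeneity=0.0, seed=7
    )


@pytest.fixture
def rich_initial():
    """Ample starting pools so constant planted rates never deplete."""
    return {m: 50.0 for m in DEFAULT_INITIAL_CONC}


@pytest.fixture(scope="session")
def study_batches():
    """One full default five-dose study (noisy, 3 replicates each)."""
    return simulate_study(default_conditions(seed=11))


def tiny_network() -> MetabolicModel:
    """A 6-reaction linear pathway with a branch, for LP oracle checks.

    A --> B --> biomass, with B alternatively lost to a sink; uptake bounded.
    """
    model = MetabolicModel(model_id="tiny")
    for mid in ("a[e]", "a[c]", "b[c]"):
        model.add_metabolite(Metabolite(mid))
    model.add_reaction(Reaction("EX_a(e)", {"a[e]": -1.0}, reversible=True, lb=-5.0, ub=0.0))
    model.add_reaction(Reaction("At", {"a[e]": -1.0, "a[c]": 1.0}, lb=0.0, ub=10.0))
    model.add_reaction(Reaction("A2B", {"a[c]": -1.0, "b[c]": 2.0}, lb=0.0, ub=4.0))
    model.add_reaction(Reaction("LOSS", {"b[c]": -1.0}, lb=0.5, ub=10.0))
    model.add_reaction(Reaction("GROW", {"b[c]": -1.0}, lb=0.0, ub=6.0))
    model.objective = "GROW"
    return model


@pytest.fixture
def tiny_model():
    return tiny_network()
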