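import numpy as np
import pytest

from neuroblankets import fixtures, models
from neuroblankets.graph import DependencyGraph


@pytest.fixture
def six_node_dag() -> DependencyGraph:
    """The hand-enumerable DAG 1->3<-2, 3->4<-5, 4->6."""
    return DependencyGraph(
        nodes=["1", "2", "3", "4", "5", "6"],
        edges=[("1", "3"), ("2", "3"), ("3", "4"), ("5", "4"), ("4", "6")],
    )


@pytest.fixture
def linear_system():
    return fixtures.random_blanket_system(seed=7)


@pytest.fixture(params=["hh", "fhn", "ml", "pair", "cmc1", "cmc2", "cmc4", "spring"])
def zoo_model(request):
    """Every shipped model with a documented role assignment."""
    return {
        "hh": lambda: models.hodgkin_huxley(),
        "fhn": lambda: models.fitzhugh_nagumo(),
        "ml": lambda: models.morris_lecar(),
        "pair": lambda: models.neural_mass_pair(),
        "cmc1": lambda: models.cmc_chain(1),
        "cmc2": lambda: models.cmc_chain(2),
        "cmc4": lambda: models.cmc_chain(4),
        "spring": lambda: fixtures.spring_chain(5),
    }[request.param]()


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
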