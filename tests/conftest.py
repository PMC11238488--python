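import pytest

from mmoa import CoreSets, ImatProblem, ToySpec, generate_toy_model


@pytest.fixture
def diamond_model():
    return generate_toy_model(ToySpec(topology="diamond", n_reactions=4, gpr_density=0.0))


@pytest.fixture
def diamond_problem(diamond_model):
    return ImatProblem(diamond_model, CoreSets(rh={"R_uptake", "R_sink"}), epsilon=1.0)


@pytest.fixture
def chain_model():
    return generate_toy_model(ToySpec(topology="chain", n_reactions=3, gpr_density=0.0))
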