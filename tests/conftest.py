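import numpy as np
import pytest

from leakyflux.fluxes import ratio_to_u
from leakyflux.label_simulation import LabelInput
from leakyflux.synthetic_data import PRESETS, make_fixture_suite


@pytest.fixture(scope="session")
def suite():
    return make_fixture_suite()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def pool_randomised_inputs(fixture, rng):
    """Fixture label inputs extended with random positional pool states.

    The steady-state solvers treat accumulating pools as boundary inputs;
    random positional distributions stress every atom pathway.
    """
    pos = dict(fixture.label_input.positional)
    for p in fixture.model.pools:
        n = fixture.model.metabolites[p].carbon_count
        d = rng.random(2**n)
        pos[p] = d / d.sum()
    return LabelInput(pos)


def true_param_vector(problem, truth, presets=PRESETS):
    """Ground-truth values in a FitProblem's packed parameter order."""
    x = []
    for name in problem.param_names:
        base, _, dsn = name.partition("[")
        dsn = dsn.rstrip("]")
        if base.startswith("v_"):
            x.append(truth.net[base[2:]])
        elif base.startswith("u_"):
            x.append(ratio_to_u(truth.reversibility_ratio(base[2:])))
        elif base.startswith("c0_"):
            design = presets[dsn] if dsn else next(iter(presets.values()))
            x.append(design.initial_conc[base[3:]])
        else:
            raise KeyError(name)
    return np.array(x)
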