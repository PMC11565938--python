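import numpy as np
import pytest

from asmtune.param_space import ParamSpace, ParamSpec, ParamVector, initial_domain
from asmtune.synthetic import make_universe, toy_space


@pytest.fixture(scope="session")
def space3():
    """Small mixed space: integer + float + binary."""
    return toy_space()


@pytest.fixture(scope="session")
def domain3(space3):
    return initial_domain(space3)


@pytest.fixture(scope="session")
def space2int():
    """Two integer coordinates with small domains, for exhaustive grids."""
    return ParamSpace(
        (
            ParamSpec("a", "integer", 3.0, warmup_step=1.0),
            ParamSpec("b", "integer", 2.0, warmup_step=1.0),
        ),
        assembler_name="grid-toy",
    )


@pytest.fixture(scope="session")
def universe_small():
    """3 planted groups x 3 samples; shared for structure-recovery tests."""
    return make_universe(n_groups=3, samples_per_group=3, seed=11)
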