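import numpy as np
import pytest

from catlasso import (
    PriorSpec,
    generate_abilities,
    generate_item_pool,
    make_group_assignment,
    study_design,
)
from catlasso.pools import StudyDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20190830)


@pytest.fixture(scope="session")
def toy_design():
    """A miniature 2-D design: 20 operational + 6 replenished items."""
    return StudyDesign(
        K=2,
        pattern_layout=(((1, 0), 7, 2), ((0, 1), 7, 2), ((1, 1), 6, 2)),
        disc_range=(1.1, 1.7),
        N=30,
        ability_cov=np.eye(2),
        Z0=8,
        Z1=3,
        n_groups=2,
    )


@pytest.fixture(scope="session")
def toy_pool(toy_design):
    return generate_item_pool(toy_design, np.random.default_rng(7))


@pytest.fixture(scope="session")
def toy_cohort_inputs(toy_design, toy_pool):
    rng = np.random.default_rng(11)
    abilities = generate_abilities(toy_design.N, toy_design.ability_cov, rng)
    assignment = make_group_assignment(toy_design, rng)
    return abilities, assignment


@pytest.fixture(scope="session")
def prior2():
    return PriorSpec.identity(2)


@pytest.fixture(scope="session")
def study1_high_design():
    return study_design("study1", "high")
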