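import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from fragsim.domain import (
    Cohort,
    CohortTable,
    ModelState,
    ReproductiveStrategy,
    Thermoregulation,
    TrophicGroup,
    all_functional_groups,
)
from fragsim.engine import ProcessParams
from fragsim.environment import (
    SeasonalityParams,
    generate_environment,
    make_landscape,
    seed_cohorts,
)


@pytest.fixture(scope="session")
def landscape3():
    """Tiny 3×3 large-cell landscape used across unit tests."""
    return make_landscape(3, 3, 0.1)


@pytest.fixture(scope="session")
def landscape5():
    return make_landscape(5, 5, 0.1)


@pytest.fixture()
def env3(landscape3):
    return generate_environment(landscape3, SeasonalityParams(), seed=7)


@pytest.fixture()
def params():
    return ProcessParams()


@pytest.fixture()
def seeded_state(landscape3):
    return seed_cohorts(
        landscape3, all_functional_groups(), n_cohorts_per_cell=2, seed=11
    )


def make_cohort(
    trophic=TrophicGroup.HERBIVORE,
    thermo=Thermoregulation.ENDOTHERM,
    repro=ReproductiveStrategy.ITEROPAROUS,
    mass=100.0,
    birth=10.0,
    maturity=100.0,
    abundance=50.0,
    cell=0,
    **kw,
):
    return Cohort(
        trophic_group=trophic,
        thermoregulation=thermo,
        reproductive_strategy=repro,
        current_mass=mass,
        birth_mass=birth,
        maturity_mass=maturity,
        abundance=abundance,
        cell_index=cell,
        **kw,
    )


@pytest.fixture()
def two_cohort_state(landscape3):
    cohorts = CohortTable.from_cohorts(
        [
            make_cohort(),
            make_cohort(trophic=TrophicGroup.CARNIVORE, mass=500.0, birth=50.0,
                        maturity=500.0, abundance=5.0),
        ]
    )
    n = landscape3.n_cells
    return ModelState(
        cohorts=cohorts,
        leaf=np.full(n, 1.0e5 * landscape3.cell_areas.mean()),
        structural=np.full(n, 2.0e4 * landscape3.cell_areas.mean()),
        leaf_strategy=np.zeros(n, dtype=np.int8),
    )
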