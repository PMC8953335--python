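import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from simisim.core import CELLS, EXPENSE_LEVELS, VISIT_TYPES
from simisim.synthetic_data import GeneratorConfig

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

#: Expense-level means with disjoint (u+0.5)-law supports (adjacent ratio > 3),
#: so within-cell quartile reassignment recovers the generating component means.
SEPARATED_MEANS = (30_000.0, 100_000.0, 330_000.0, 1_100_000.0)


def make_config(
    n_persons: int = 2_000,
    seed: int = 7,
    rate: float | dict = 40.0,
    visit_triple=(0.2, 0.3, 0.5),
    means=SEPARATED_MEANS,
    growth: float = 0.02,
    shares=(0.56, 0.29, 0.15),
    cell_probs=None,
    years=(2011, 2016),
    **overrides,
) -> GeneratorConfig:
    """A compact, fully specified generator configuration for tests.

    ``rate`` may be a scalar (percent, constant over years) or a
    {year: percent} mapping applied to every cell.
    """
    year_range = range(years[0], years[1] + 1)
    rate_by_year = rate if isinstance(rate, dict) else {y: rate for y in year_range}
    return GeneratorConfig(
        n_persons=n_persons,
        seed=seed,
        years=years,
        cell_probs=cell_probs or {c: 0.25 for c in CELLS},
        admission_rates={c: dict(rate_by_year) for c in CELLS},
        visit_probs={c: {y: visit_triple for y in year_range} for c in CELLS},
        mean_costs={
            (g, a, lev, vt): means[lev - 1]
            for g, a in CELLS for lev in EXPENSE_LEVELS for vt in VISIT_TYPES
        },
        growth={
            (g, a, lev, vt): growth
            for g, a in CELLS for lev in EXPENSE_LEVELS for vt in VISIT_TYPES
        },
        shares={
            (g, a, lev, vt): shares
            for g, a in CELLS for lev in EXPENSE_LEVELS for vt in VISIT_TYPES
        },
        **overrides,
    )


@pytest.fixture
def config_factory():
    return make_config


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)
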