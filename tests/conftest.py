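"""Shared fixtures: small simulated cohorts and a fast EA configuration."""

import pytest

from evohdtree import EAConfig
from evohdtree.io import filter_by_presence, impute_half_lod, make_comparison
from evohdtree.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-sample two-group cohort with the default planted effects."""
    return simulate(SimConfig(group_sizes={"GIV": 15, "Con": 15}, seed=11))


@pytest.fixture(scope="session")
def small_comparison(small_cohort):
    m, _ = small_cohort
    return make_comparison(impute_half_lod(filter_by_presence(m)), ["GIV"], ["Con"])


@pytest.fixture
def quick_config():
    """A deliberately tiny search budget for smoke-level evolution tests."""
    return EAConfig(
        population_size=12,
        generations=6,
        stagnation_limit=4,
        max_depth=3,
        init_depth_range=(1, 2),
        seed=3,
    )
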