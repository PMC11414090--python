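import numpy as np
import pytest

from callimorph.stats_core import GroupSummary
from callimorph.synthetic_data import (
    HybridSpec,
    SyntheticScenario,
    default_scenario,
    generate_traits,
)


def make_summary(group, n, mean, sd, trait="X"):
    return GroupSummary(group=group, trait=trait, n=n, mean=mean, sd=sd)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def study_scale_synthetic():
    """Study-scale synthetic dataset: 209 individuals over 8 taxa."""
    return generate_traits(default_scenario(seed=7))


@pytest.fixture
def small_scenario():
    """Three-group scenario with one heterotic hybrid, fast to generate."""
    parental = {
        "J": {t: (20.0, 2.0) for t in _traits()},
        "P": {t: (26.0, 2.0) for t in _traits()},
    }
    return SyntheticScenario(
        parental_specs=parental,
        hybrid_specs={"PJ": HybridSpec(parents=("J", "P"), regime="heterotic", effect_size=1.0)},
        group_sizes={"J": 40, "P": 40, "PJ": 40},
        seed=11,
    )


def _traits():
    from callimorph.schema import TRAIT_NAMES

    return TRAIT_NAMES
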