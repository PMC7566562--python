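import random

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from rrnaprobe.candidates import DesignConfig
from rrnaprobe.synthetic import FixtureRecipe, make_target
from rrnaprobe.targets import ConsensusTarget
from rrnaprobe.thermo import ThermoConfig


@pytest.fixture
def rng():
    return random.Random(20240601)


@pytest.fixture
def nprng():
    return np.random.default_rng(20240601)


@pytest.fixture
def thermo_cfg():
    return ThermoConfig()


@pytest.fixture
def design_cfg():
    return DesignConfig()


@pytest.fixture
def recipe():
    return FixtureRecipe(seed=101, target_length=2000, decoy_count=12,
                         planted_match_lengths=[16, 12])


@pytest.fixture
def target_seq(recipe):
    return make_target(recipe)


@pytest.fixture
def consensus(target_seq):
    return ConsensusTarget("syn_target", target_seq)


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(alphabet) for _ in range(n))
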