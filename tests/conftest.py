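import numpy as np
import pytest

from klchoice import (
    ModelSpec,
    Option,
    PrecisionMode,
    PrecisionPrior,
    TrialOffer,
    UtilityProfile,
    Valuation,
)
from klchoice.synth import AgentSpec, DesignSpec, generate_design, random_agent


@pytest.fixture
def profile():
    """A 6-outcome utility profile inside the fitting box, outcome 1 pinned."""
    return UtilityProfile.from_vector([0.0, 2.5, -3.0, 1.0, -1.5, 4.0])


@pytest.fixture
def flat_profile():
    return UtilityProfile.from_vector([0.0] * 6)


@pytest.fixture
def kl_spec():
    return ModelSpec(Valuation.KL_CONTROL, PrecisionMode.ESTIMATED)


@pytest.fixture
def eu_spec():
    return ModelSpec(Valuation.EXPECTED_UTILITY, PrecisionMode.ESTIMATED)


@pytest.fixture
def kl_agent(profile, kl_spec):
    return AgentSpec(
        utilities=profile,
        precision_prior=PrecisionPrior(4.0),
        model=kl_spec,
        rating_noise_sd=0.3,
    )


@pytest.fixture
def small_design():
    """A reduced design for fast fitting tests."""
    return DesignSpec(n_trials=120)


def random_option(rng, universe_size=6, max_size=4):
    k = int(rng.integers(1, max_size + 1))
    ids = rng.choice(np.arange(1, universe_size + 1), size=k, replace=False)
    return Option(ids.tolist())


def random_profile(rng, universe_size=6):
    u = rng.uniform(-10, 10, size=universe_size)
    u[0] = 0.0
    return UtilityProfile.from_vector(u)
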