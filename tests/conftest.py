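import numpy as np
import pandas as pd
import pytest

from rmc.simulate import SimProfile, simulate_transcript_model


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def two_region_model():
    """Transcript with a planted constrained/neutral split at position 75."""
    profile = SimProfile(
        n_sites=150, n_alts=2, mu_adj=0.4, boundaries=(75,), region_oe=(0.2, 1.0)
    )
    tm, truth = simulate_transcript_model(profile, seed=11)
    return tm, truth


@pytest.fixture
def uniform_model():
    """Transcript with no regional structure (OE 1 everywhere)."""
    profile = SimProfile(n_sites=150, n_alts=2, mu_adj=0.4)
    tm, truth = simulate_transcript_model(profile, seed=4)
    return tm, truth


def random_transcript_model(seed, n_positions=120, mu=0.3):
    """Random-OE transcript used by oracle-equivalence tests."""
    rng = np.random.default_rng(seed)
    n_regions = rng.integers(1, 4)
    bounds = tuple(
        sorted(rng.choice(np.arange(10, n_positions - 10), n_regions - 1, replace=False))
    )
    oes = tuple(rng.uniform(0.05, 1.0, n_regions))
    profile = SimProfile(
        n_sites=n_positions, n_alts=2, mu_adj=mu, boundaries=bounds, region_oe=oes
    )
    return simulate_transcript_model(profile, seed=int(rng.integers(0, 2**31)))[0]
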