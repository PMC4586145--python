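import numpy as np
import pytest

from phyllopart.synthetic import GeneratorConfig


@pytest.fixture
def small_config():
    """A small but non-trivial generator configuration for fast tests."""
    return GeneratorConfig(n_host=60, n_symbiont=60, n_samples=22,
                           n_families=4, family_size=4, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_dna(rng, length, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))
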