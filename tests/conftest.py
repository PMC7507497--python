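import warnings

import pytest

from agox.simulate import (
    SimConfig,
    gen_counts,
    gen_image_stacks,
    gen_msa,
    gen_transcriptome,
)


@pytest.fixture(scope="session")
def transcriptome():
    """Default synthetic transcriptome (100 transcripts, 5 planted conserved)."""
    return gen_transcriptome(SimConfig(seed=1))


@pytest.fixture(scope="session")
def tarsier_msa():
    """The tarsier-like alignment preset: one 3-nt deletion, no nonsense."""
    return gen_msa(SimConfig(seed=1), preset="tarsier_like")


@pytest.fixture(scope="session")
def sim_counts():
    """Default synthetic count matrices with 1% enriched + 1% depleted genes."""
    return gen_counts(SimConfig(seed=2))


@pytest.fixture(scope="session")
def sim_stacks():
    """Default 20-cell image stacks at the default nucleolar factor."""
    return gen_image_stacks(SimConfig(seed=1))


@pytest.fixture(autouse=True)
def _no_warning_noise():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        yield
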