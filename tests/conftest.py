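import numpy as np
import pytest

from pgtsr import (
    RunConfig, TranslocationSpec, hg19_genome, make_derivatives, make_family,
    make_panel, toy_genome,
)


@pytest.fixture(scope="session")
def genome():
    return toy_genome(seed=0)


@pytest.fixture(scope="session")
def hg19():
    return hg19_genome()


@pytest.fixture(scope="session")
def spec():
    # q/q exchange on the toy genome, with junction micro-insertions
    return TranslocationSpec(
        "chr1", 3_500_000, "chr2", 4_200_000, armA="q", armB="q",
        insertionA="ACGTTGCA", insertionB="GATTACA",
    )


@pytest.fixture(scope="session")
def mixed_spec():
    # p-arm / q-arm exchange, one derivative segment inverted
    return TranslocationSpec("chr3", 1_500_000, "chr4", 6_000_000, armA="p", armB="q")


@pytest.fixture(scope="session")
def derivatives(genome, spec):
    return make_derivatives(genome, spec)


@pytest.fixture(scope="session")
def panel(genome):
    return make_panel(genome, density_per_mb=40.0, seed=1)


@pytest.fixture(scope="session")
def family(genome, panel, spec):
    return make_family(genome, panel, spec, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
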