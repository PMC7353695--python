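import numpy as np
import pytest

from coalabc import DemographicScenario, GenotypeMatrix, ModelKind, SampleSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def constant_scenario():
    return DemographicScenario(kind=ModelKind.CONSTANT, Nc=1000)


@pytest.fixture
def expansion_scenario():
    return DemographicScenario(
        kind=ModelKind.EXPANSION_LGM, NA=10_000, N=100_000, TEXP=28_000
    )


@pytest.fixture
def small_spec():
    return SampleSpec(n_diploid=6, n_snp_loci=40, n_seq_loci=2, seq_locus_length=140)


def make_genotypes(rows, individuals=None, loci=None) -> GenotypeMatrix:
    """Small helper: build a GenotypeMatrix from a nested list of codes."""
    geno = np.asarray(rows, dtype=np.int8)
    n_ind, n_loc = geno.shape
    return GenotypeMatrix(
        genotypes=geno,
        individuals=individuals or [f"i{k}" for k in range(n_ind)],
        loci=loci or [f"L{k}" for k in range(n_loc)],
    )
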