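"""Shared fixtures: tiny deterministic genomes and individuals."""

import pytest

from refeditor.diploid_constructor import BuildParameters
from refeditor.io_formats import ReferenceGenome, VariantRecord
from refeditor.synthetic_data import generate_genome, sample_individual


@pytest.fixture(scope="session")
def toy_genome() -> ReferenceGenome:
    """1-kb single-chromosome random genome."""
    return generate_genome(1, [1000], seed=11)


@pytest.fixture(scope="session")
def small_genome() -> ReferenceGenome:
    """10-kb genome for mapping-level tests."""
    return generate_genome(1, [10000], seed=12)


@pytest.fixture(scope="session")
def small_individual(small_genome):
    return sample_individual(
        small_genome, snp_rate=0.01, indel_rate=0.001, het_fraction=0.6,
        seed=13,
    )


@pytest.fixture
def params36() -> BuildParameters:
    """The short-read setting used throughout: 36-bp reads, <=2-bp indels."""
    return BuildParameters(k=36, m=2)


def het_snp(chrom, pos, ref, alt):
    return VariantRecord(chrom, pos, ref, (alt,), (0, 1))


def hom_snp(chrom, pos, ref, alt):
    return VariantRecord(chrom, pos, ref, (alt,), (1, 1))
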