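import numpy as np
import pytest

from hemotyper.genotype_io import Genotype, GenotypeRecord
from hemotyper.knowledge_base import load_demo_table


@pytest.fixture(scope="session")
def abo_table():
    """The bundled ABO excerpt: A101/A102/O02/B101 over three chr9 loci."""
    return load_demo_table()


def make_genotype(records, sample_id="sample", assembly="hg19"):
    """Genotype from (chrom, pos, allele_a, allele_b) tuples."""
    genotype = Genotype(sample_id=sample_id, assembly=assembly)
    for chrom, pos, a, b in records:
        genotype.add(GenotypeRecord(chrom, pos, a, b))
    return genotype


@pytest.fixture
def ab_diplotype_genotype():
    """Planted A102/B101 diplotype on the demo table: hom GG, het C/T, het G/A."""
    return make_genotype(
        [
            ("9", 136132908, "GG", "GG"),
            ("9", 136131650, "C", "T"),
            ("9", 136131414, "G", "A"),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
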