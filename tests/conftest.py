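import numpy as np
import pytest

from gpcomp import SimConfig, simulate, simulate_genotypes
from gpcomp.genotype_io import GenotypeMatrix, Marker


@pytest.fixture(scope="session")
def small_panel():
    """Unrelated panel: 120 individuals x 300 SNPs, h2=0.5."""
    return simulate(
        SimConfig(n_individuals=120, m_snps=300, n_qtl=30, h2=0.5, seed=3)
    )


@pytest.fixture(scope="session")
def tiny_genotypes():
    """40 x 30 genotype matrix with no missing entries."""
    return simulate_genotypes(
        SimConfig(n_individuals=40, m_snps=30, n_qtl=5, seed=0)
    )


@pytest.fixture
def toy_matrix():
    """3 individuals x 2 SNPs used in hand-arithmetic oracles."""
    return GenotypeMatrix(
        np.array([[0, 2], [1, 1], [2, 0]], dtype=np.int8),
        ["a", "b", "c"],
        [Marker("s1"), Marker("s2")],
    )


def write_vcf(path, sample_ids, records):
    """Minimal VCF v4.2 writer for fixtures.

    ``records`` rows: (chrom, pos, vid, ref, alt, [gt strings]).
    """
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1>",
        "##contig=<ID=2>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_ids),
    ]
    for chrom, pos, vid, ref, alt, gts in records:
        lines.append(
            f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return path
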