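import pytest

from seqtally import refdb, synth
from seqtally.readstore import ExperimentDesign, Replicate

# Two genes on one 360-nt contig; gene A has two isoforms sharing exon1 and
# exon3 (isoform 2 skips exon2). Coordinates are 1-based inclusive in GFF3.
TINY_FASTA = ">chr1\n" + "\n".join(
    [
        # deterministic but non-repetitive sequence
        "".join("ACGT"[(7 * i + 3 * (i // 4)) % 4] for i in range(j, j + 60))
        for j in range(0, 360, 60)
    ]
) + "\n"

TINY_GFF3 = """##gff-version 3
chr1\ttest\tgene\t11\t190\t.\t+\t.\tID=geneA
chr1\ttest\tmRNA\t11\t190\t.\t+\t.\tID=geneA.1;Parent=geneA
chr1\ttest\tmRNA\t11\t190\t.\t+\t.\tID=geneA.2;Parent=geneA
chr1\ttest\texon\t11\t70\t.\t+\t.\tParent=geneA.1,geneA.2
chr1\ttest\texon\t91\t130\t.\t+\t.\tParent=geneA.1
chr1\ttest\texon\t151\t190\t.\t+\t.\tParent=geneA.1,geneA.2
chr1\ttest\tgene\t221\t340\t.\t-\t.\tID=geneB
chr1\ttest\tmRNA\t221\t340\t.\t-\t.\tID=geneB.1;Parent=geneB
chr1\ttest\texon\t221\t270\t.\t-\t.\tParent=geneB.1
chr1\ttest\texon\t301\t340\t.\t-\t.\tParent=geneB.1
"""


@pytest.fixture(scope="session")
def tiny_catalog():
    cat = refdb.load_reference_strings(TINY_FASTA, TINY_GFF3)
    refdb.build_junctions(cat, flank=20)
    return cat


@pytest.fixture(scope="session")
def design_3x3():
    return ExperimentDesign(
        [Replicate(f"mock_{i}", "mock") for i in (1, 2, 3)]
        + [Replicate(f"trt_{i}", "treated") for i in (1, 2, 3)]
    )


@pytest.fixture(scope="session")
def small_dataset(design_3x3):
    """40-gene genome with reads, error-free, for pipeline-level tests."""
    truth = synth.make_genome(n_genes=40, length=60_000, seed=11)
    reads = synth.make_reads(
        truth, design_3x3, depth=6_000, read_length=25, mismatch_rate=0.0,
        fold=4.0, de_fraction=0.1, phi=0.1, alpha=2.0, seed=12,
    )
    cat = refdb.load_reference_strings(truth.fasta_text, truth.gff3_text)
    refdb.build_junctions(cat, flank=24)
    return truth, cat, reads
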