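import numpy as np
import pandas as pd
import pytest

from bsasweep import CrossConfig, PanelConfig, sample_bulk_counts, simulate_cross, simulate_panel
from bsasweep.variant_io import MarkerTable


@pytest.fixture(scope="session")
def small_cross():
    """A default-size cross with deep truth, shared across tests."""
    cfg = CrossConfig(seed=7)
    truth = simulate_cross(cfg)
    counts = sample_bulk_counts(truth)
    return cfg, truth, counts


@pytest.fixture(scope="session")
def sweep_panel():
    """Default two-population panel with the truth sweep interval."""
    cfg = PanelConfig(seed=7)
    return cfg, simulate_panel(cfg)


@pytest.fixture
def random_marker_table():
    """Factory for random single-chromosome marker tables."""

    def make(n=1000, chrom_length=5_000_000, seed=0, depth_mean=30):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(np.arange(1, chrom_length + 1), n, replace=False))
        rows = {"chrom": "chrX", "pos": pos, "variant_type": "SNP"}
        for s in ("P_P50", "P_Wild", "bulk_pos", "bulk_neg"):
            depth = np.maximum(rng.poisson(depth_mean, n), 1)
            nonref = rng.binomial(depth, rng.random(n))
            rows[f"{s}_ref"] = depth - nonref
            rows[f"{s}_nonref"] = nonref
        return MarkerTable(
            pd.DataFrame(rows), ("P_P50", "P_Wild"), ("bulk_pos", "bulk_neg")
        )

    return make


@pytest.fixture
def toy_genome_files(tmp_path):
    """Small FASTA + GFF3 on disk: one plus-strand and one minus-strand gene.

    geneA (+): CDS 11..19 = ATGGGTTAA -> protein MG*.
    geneB (-): CDS 31..39 whose reverse complement is ATGGGTTAA.
    geneC (+): two CDS exons split mid-codon, spliced CDS = ATGGGTTAA.
    """
    seq = list("ACGT" * 30)  # 120 bp scaffold
    seq[10:19] = "ATGGGTTAA"
    seq[30:39] = "TTAACCCAT"  # revcomp = ATGGGTTAA
    seq[50:55] = "ATGGG"  # exon 1 of geneC (split mid-codon)
    seq[60:64] = "TTAA"  # exon 2 of geneC
    fasta = tmp_path / "toy.fa"
    fasta.write_text(">chr1\n" + "".join(seq) + "\n")
    gff = tmp_path / "toy.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\ttest\tgene\t5\t25\t.\t+\t.\tID=geneA\n"
        "chr1\ttest\tmRNA\t5\t25\t.\t+\t.\tID=geneA.t1;Parent=geneA\n"
        "chr1\ttest\tCDS\t11\t19\t.\t+\t0\tID=geneA.c1;Parent=geneA.t1\n"
        "chr1\ttest\tgene\t31\t39\t.\t-\t.\tID=geneB\n"
        "chr1\ttest\tmRNA\t31\t39\t.\t-\t.\tID=geneB.t1;Parent=geneB\n"
        "chr1\ttest\tCDS\t31\t39\t.\t-\t0\tID=geneB.c1;Parent=geneB.t1\n"
        "chr1\ttest\tgene\t51\t64\t.\t+\t.\tID=geneC\n"
        "chr1\ttest\tmRNA\t51\t64\t.\t+\t.\tID=geneC.t1;Parent=geneC\n"
        "chr1\ttest\tCDS\t51\t55\t.\t+\t0\tID=geneC.c1;Parent=geneC.t1\n"
        "chr1\ttest\tCDS\t61\t64\t.\t+\t1\tID=geneC.c2;Parent=geneC.t1\n"
    )
    return fasta, gff
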