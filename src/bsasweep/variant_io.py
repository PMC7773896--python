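"""Variant and annotation input, and marker selection for index scans.

The mapping design is a backcross between a recessive reference strain
(P50) and an F1 carrier of the wild haplotype.  Sites that are homozygous
in both parents, for different alleles, are the informative markers: in
the bulks, the fraction of reads carrying the non-P50 allele is the
SNP/InDel index.  This module reads per-sample allele depths (the VCF AD
field), applies the marker-selection filters, and re-expresses every
retained site so that "reference" means the P50 parent's allele.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

HOM_REF = "hom-ref"
HOM_ALT = "hom-alt"
HET = "het"
MISSING = "missing"

SNP = "SNP"
INDEL = "InDel"


class VCFFormatError(ValueError):
    """The VCF lacks a required field (e.g. AD) or is malformed."""


class SampleNotFoundError(KeyError):
    """A requested sample name is absent from the input."""


@dataclass
class AlleleCountRecord:
    """One variant site with per-sample ref / non-ref read counts.

    ``genotypes`` carries the called genotype per sample (parents are the
    ones that matter downstream); bulks are pooled so their genotype is
    usually ``missing`` while their counts are informative.
    """

    chrom: str
    pos: int  # 1-based
    variant_type: str  # SNP or InDel
    ref_counts: dict[str, int]
    nonref_counts: dict[str, int]
    genotypes: dict[str, str] = field(default_factory=dict)
    ref: str = "N"
    alt: str = "N"

    def depth(self, sample: str) -> int:
        return self.ref_counts.get(sample, 0) + self.nonref_counts.get(sample, 0)


@dataclass
class MarkerTable:
    """Filtered informative markers with per-sample counts.

    ``df`` columns: chrom, pos, variant_type, then ``{sample}_ref`` and
    ``{sample}_nonref`` for parents and bulks.  Counts are oriented so the
    reference allele is the P50 parent's allele.  ``filters`` records the
    provenance of the applied selection.
    """

    df: pd.DataFrame
    parents: tuple[str, str]  # (P50-like recessive parent, wild parent)
    bulks: tuple[str, ...]
    filters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = self.df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def samples(self) -> tuple[str, ...]:
        return self.parents + self.bulks

    def positions(self, chrom: str | None = None) -> np.ndarray:
        df = self.df if chrom is None else self.df[self.df.chrom == chrom]
        return df.pos.to_numpy(dtype=np.int64)

    def counts(self, sample: str, chrom: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(ref, nonref) count vectors for one sample."""
        df = self.df if chrom is None else self.df[self.df.chrom == chrom]
        return (
            df[f"{sample}_ref"].to_numpy(dtype=np.int64),
            df[f"{sample}_nonref"].to_numpy(dtype=np.int64),
        )

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df.chrom))

    def restrict(self, chrom: str) -> "MarkerTable":
        return MarkerTable(
            self.df[self.df.chrom == chrom].copy(), self.parents, self.bulks, self.filters
        )

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def _genotype_label(alleles: list[int]) -> str:
    calls = [a for a in alleles[:2]]
    if any(a < 0 for a in calls) or not calls:
        return MISSING
    if all(a == 0 for a in calls):
        return HOM_REF
    if all(a == calls[0] for a in calls):
        return HOM_ALT
    return HET


def read_variants(
    vcf_path: str | os.PathLike,
    multiallelic: str = "skip",
) -> Iterator[AlleleCountRecord]:
    """Stream allele-count records from a VCF with per-sample AD.

    Multiallelic sites are skipped by default (the index statistic is
    defined for two allele classes); ``multiallelic="error"`` raises
    instead.  A sample record with no AD yields zero counts and a missing
    genotype; a file whose FORMAT lacks AD entirely is a hard error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if "AD" not in {f["ID"] for f in _format_headers(vcf)}:
        raise VCFFormatError(
            f"VCF {vcf_path} declares no AD FORMAT field (samples: {samples})"
        )
    for i, v in enumerate(vcf):
        if len(v.ALT) != 1:
            if multiallelic == "skip":
                continue
            raise VCFFormatError(
                f"multiallelic site at {v.CHROM}:{v.POS} (record {i + 1})"
            )
        ad = v.format("AD")
        if ad is None:
            raise VCFFormatError(
                f"missing AD at {v.CHROM}:{v.POS} for samples {samples}"
            )
        ad = np.asarray(ad)
        ref_counts, nonref_counts, genotypes = {}, {}, {}
        for j, s in enumerate(samples):
            r = int(ad[j, 0]) if ad.shape[1] >= 1 else -1
            a = int(ad[j, 1]) if ad.shape[1] >= 2 else -1
            gt = _genotype_label(list(v.genotypes[j])[:2])
            if r < 0 or a < 0:  # AD missing for this sample
                r, a, gt = 0, 0, MISSING
            ref_counts[s], nonref_counts[s], genotypes[s] = r, a, gt
        vt = SNP if len(v.REF) == 1 and len(v.ALT[0]) == 1 else INDEL
        yield AlleleCountRecord(
            chrom=v.CHROM,
            pos=v.POS,
            variant_type=vt,
            ref_counts=ref_counts,
            nonref_counts=nonref_counts,
            genotypes=genotypes,
            ref=v.REF,
            alt=v.ALT[0],
        )


def _format_headers(vcf) -> list[dict]:
    out = []
    for h in vcf.header_iter():
        try:
            if h["HeaderType"] == "FORMAT":
                out.append(h)
        except KeyError:
            continue
    return out


def select_markers(
    records: Iterable[AlleleCountRecord],
    parent_p50: str,
    parent_wild: str,
    bulks: Iterable[str],
    min_parent_depth: int = 7,
    min_bulk_depth: int = 7,
) -> MarkerTable:
    """Apply the marker-selection filters and build a :class:`MarkerTable`.

    A site is retained when (a) both parents are homozygous for different
    alleles, (b) each parent is covered by at least ``min_parent_depth``
    reads, and (c) the bulks are informative: a site is dropped only when
    *both* bulks are below ``min_bulk_depth`` or when any bulk has no
    coverage at all (missing).  Retained sites are re-oriented so the
    reference allele is the P50 parent's allele: where P50 was called
    hom-alt against the assembly, ref and non-ref counts are swapped for
    every sample.
    """
    bulks = tuple(bulks)
    rows = []
    n_input = 0
    excluded = {"parent_genotype": 0, "parent_depth": 0, "bulk_depth": 0}
    for rec in records:
        n_input += 1
        for s in (parent_p50, parent_wild) + bulks:
            if s not in rec.ref_counts:
                raise SampleNotFoundError(
                    f"sample {s!r} not present at {rec.chrom}:{rec.pos}"
                )
        gt50 = rec.genotypes.get(parent_p50, MISSING)
        gtw = rec.genotypes.get(parent_wild, MISSING)
        if not (
            gt50 in (HOM_REF, HOM_ALT)
            and gtw in (HOM_REF, HOM_ALT)
            and gt50 != gtw
        ):
            excluded["parent_genotype"] += 1
            continue
        if (
            rec.depth(parent_p50) < min_parent_depth
            or rec.depth(parent_wild) < min_parent_depth
        ):
            excluded["parent_depth"] += 1
            continue
        depths = [rec.depth(b) for b in bulks]
        if any(d == 0 for d in depths) or all(d < min_bulk_depth for d in depths):
            excluded["bulk_depth"] += 1
            continue
        swap = gt50 == HOM_ALT
        row = {"chrom": rec.chrom, "pos": rec.pos, "variant_type": rec.variant_type}
        for s in (parent_p50, parent_wild) + bulks:
            r, a = rec.ref_counts[s], rec.nonref_counts[s]
            if swap:
                r, a = a, r
            row[f"{s}_ref"], row[f"{s}_nonref"] = r, a
        rows.append(row)

    columns = ["chrom", "pos", "variant_type"]
    for s in (parent_p50, parent_wild) + bulks:
        columns += [f"{s}_ref", f"{s}_nonref"]
    df = pd.DataFrame(rows, columns=columns)
    return MarkerTable(
        df=df,
        parents=(parent_p50, parent_wild),
        bulks=bulks,
        filters={
            "min_parent_depth": min_parent_depth,
            "min_bulk_depth": min_bulk_depth,
            "n_input": n_input,
            "n_retained": len(df),
            "n_excluded": excluded,
            "reference_orientation": parent_p50,
        },
    )


# ---------------------------------------------------------------------------
# Gene models and genome access


@dataclass
class GeneModel:
    """A single-isoform protein-coding gene model.

    ``cds`` holds 1-based inclusive intervals in genome order; minus-strand
    models are reverse-complemented on extraction.  ``tx_start``/``tx_end``
    bound the transcript (for UTR calls); when absent they default to the
    CDS span.  Models whose total CDS length is not a multiple of 3 are
    ``flagged`` and excluded from effect calls.
    """

    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    cds: list[tuple[int, int]]
    tx_start: int | None = None
    tx_end: int | None = None
    flagged: bool = False

    def __post_init__(self) -> None:
        self.cds = sorted((int(a), int(b)) for a, b in self.cds)
        for (a1, b1), (a2, _) in zip(self.cds, self.cds[1:]):
            if a2 <= b1:
                raise ValueError(f"overlapping CDS intervals in {self.gene_id}")
        if self.tx_start is None:
            self.tx_start = self.cds[0][0]
        if self.tx_end is None:
            self.tx_end = self.cds[-1][1]
        if self.cds_length % 3 != 0:
            self.flagged = True

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds)

    @property
    def span(self) -> tuple[int, int]:
        return self.tx_start, self.tx_end


def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Genome slice, 1-based inclusive; accepts pyfaidx.Fasta or a mapping."""
    if hasattr(genome, "keys") and isinstance(genome, Mapping):
        seq = genome[chrom]
        return str(seq[start - 1 : end]).upper()
    # pyfaidx.Fasta: record slicing is 0-based half-open
    return str(genome[chrom][start - 1 : end]).upper()


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def cds_sequence(model: GeneModel, genome) -> str:
    """Spliced coding sequence, 5'→3' in transcription orientation."""
    parts = [fetch_sequence(genome, model.chrom, a, b) for a, b in model.cds]
    seq = "".join(parts)
    return reverse_complement(seq) if model.strand == "-" else seq


def translate_cds(model: GeneModel, genome) -> str:
    """Protein from the spliced CDS (standard nuclear code, stop = '*')."""
    from Bio.Seq import Seq

    return str(Seq(cds_sequence(model, genome)).translate())


def read_gene_models(
    gff3_path: str | os.PathLike,
    fasta_path: str | os.PathLike | None = None,
):
    """Load gene models from GFF3 (and genome from FASTA, if given).

    Returns ``(models, genome)``; ``genome`` is ``None`` when no FASTA is
    supplied.  Models whose CDS length is not divisible by 3 come back
    flagged; a CDS referencing a chromosome absent from the FASTA raises.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genome = None
    if fasta_path is not None:
        from pyfaidx import Fasta

        genome = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)

    models: list[GeneModel] = []
    parents = list(db.features_of_type("mRNA"))
    if not parents:
        parents = list(db.features_of_type("gene"))
    for feat in parents:
        cds = sorted(
            ((c.start, c.end) for c in db.children(feat, featuretype="CDS")),
        )
        if not cds:
            continue
        if genome is not None and feat.seqid not in genome.keys():
            raise ValueError(
                f"gene {feat.id}: chromosome {feat.seqid!r} absent from FASTA"
            )
        models.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                strand=feat.strand,
                cds=cds,
                tx_start=feat.start,
                tx_end=feat.end,
            )
        )
    return models, genome
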