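"""Coding-effect classification of variants against gene models.

A CDS SNP is classified by mutating its codon and comparing the encoded
amino acids (synonymous / non-synonymous / stop-gain / stop-loss); simple
indels are classified by length (frameshift vs in-frame).  Protein
changes are reported as refAA + 1-based residue + altAA, e.g. ``G115D``
for a glycine→aspartate substitution at residue 115, numbering from the
initiator methionine.
"""
from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .variant_io import (
    GeneModel,
    cds_sequence,
    fetch_sequence,
    reverse_complement,
)

__all__ = [
    "EffectCall",
    "ReferenceMismatchError",
    "classify_variant",
    "divergent_nonsynonymous",
]

CODING_SNP_EFFECTS = ("synonymous", "non-synonymous", "stop-gain", "stop-loss")


class ReferenceMismatchError(ValueError):
    """The variant's stated reference allele disagrees with the genome."""


@dataclass
class EffectCall:
    """Predicted consequence of one variant on one transcript."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str | None
    effect: str
    protein_change: str | None = None
    freq_dom: float | None = None
    freq_wild: float | None = None


def _cds_offset(model: GeneModel, pos: int) -> int | None:
    """0-based offset of ``pos`` in the spliced CDS (genome order), or None."""
    off = 0
    for a, b in model.cds:
        if a <= pos <= b:
            return off + (pos - a)
        off += b - a + 1
    return None


def _aa_compare(ref_aa: str, alt_aa: str) -> str:
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "stop-gain"
    if ref_aa == "*":
        return "stop-loss"
    return "non-synonymous"


def _classify_snp(model: GeneModel, genome, pos: int, ref: str, alt: str) -> EffectCall:
    offset = _cds_offset(model, pos)
    assert offset is not None
    cds = cds_sequence(model, genome)
    if model.strand == "-":
        cds_pos = len(cds) - 1 - offset
        alt_base = reverse_complement(alt)
    else:
        cds_pos = offset
        alt_base = alt.upper()
    codon_i = cds_pos // 3
    within = cds_pos % 3
    codon = cds[3 * codon_i : 3 * codon_i + 3]
    ref_aa = str(Seq(codon).translate())
    new_codon = codon[:within] + alt_base + codon[within + 1 :]
    alt_aa = str(Seq(new_codon).translate())
    effect = _aa_compare(ref_aa, alt_aa)
    change = f"{ref_aa}{codon_i + 1}{alt_aa}"
    return EffectCall(
        chrom=model.chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene_id=model.gene_id,
        effect=effect,
        protein_change=change,
    )


def _inframe_change(model: GeneModel, genome, pos: int, ref: str, alt: str) -> str | None:
    """Protein-change notation for an in-frame indel by full-protein diff.

    Returns None when the edit cannot be placed within a single CDS
    interval (splice-spanning events are out of scope).
    """
    for a, b in model.cds:
        if a <= pos and pos + len(ref) - 1 <= b:
            break
    else:
        return None
    # Rebuild the spliced CDS with the edit applied in genome orientation.
    parts = []
    for a, b in model.cds:
        seq = fetch_sequence(genome, model.chrom, a, b)
        if a <= pos <= b:
            i = pos - a
            seq = seq[:i] + alt.upper() + seq[i + len(ref) :]
        parts.append(seq)
    mutated = "".join(parts)
    if model.strand == "-":
        mutated = reverse_complement(mutated)
    prot_ref = str(Seq(cds_sequence(model, genome)).translate())
    prot_alt = str(Seq(mutated).translate())
    if prot_ref == prot_alt:
        return None
    i = 0
    while i < min(len(prot_ref), len(prot_alt)) and prot_ref[i] == prot_alt[i]:
        i += 1
    j = 0
    while (
        j < min(len(prot_ref), len(prot_alt)) - i
        and prot_ref[len(prot_ref) - 1 - j] == prot_alt[len(prot_alt) - 1 - j]
    ):
        j += 1
    ref_seg = prot_ref[i : len(prot_ref) - j] or "-"
    alt_seg = prot_alt[i : len(prot_alt) - j] or "-"
    return f"{ref_seg}{i + 1}{alt_seg}"


def classify_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    gene_models: list[GeneModel],
    genome,
) -> list[EffectCall]:
    """Classify one variant against every overlapping gene model.

    Returns one call per overlapping transcript (flagged models are
    skipped); a variant overlapping no model yields a single intergenic
    call.  Within a transcript: CDS → codon comparison (SNP) or
    frameshift/in-frame (indel); between CDS intervals → intronic; within
    the transcript span but outside the CDS region → UTR.  The genome
    base at ``pos`` must equal ``ref``.
    """
    ref = ref.upper()
    alt = alt.upper()
    genome_base = fetch_sequence(genome, chrom, pos, pos + len(ref) - 1)
    if genome_base != ref:
        raise ReferenceMismatchError(
            f"{chrom}:{pos} reference {ref!r} does not match genome {genome_base!r}"
        )

    calls: list[EffectCall] = []
    for model in gene_models:
        if model.chrom != chrom or model.flagged:
            continue
        lo, hi = model.span
        if not lo <= pos <= hi:
            continue
        in_cds = _cds_offset(model, pos) is not None
        cds_lo, cds_hi = model.cds[0][0], model.cds[-1][1]
        if in_cds:
            if len(ref) == 1 and len(alt) == 1:
                calls.append(_classify_snp(model, genome, pos, ref, alt))
            else:
                shift = abs(len(alt) - len(ref))
                if shift % 3 != 0:
                    effect, change = "frameshift", None
                else:
                    effect = "inframe-indel"
                    change = _inframe_change(model, genome, pos, ref, alt)
                calls.append(
                    EffectCall(chrom, pos, ref, alt, model.gene_id, effect, change)
                )
        elif cds_lo <= pos <= cds_hi:
            calls.append(EffectCall(chrom, pos, ref, alt, model.gene_id, "intronic"))
        else:
            calls.append(EffectCall(chrom, pos, ref, alt, model.gene_id, "UTR"))
    if not calls:
        calls.append(EffectCall(chrom, pos, ref, alt, None, "intergenic"))
    return calls


def divergent_nonsynonymous(
    effect_calls: list[EffectCall],
    frequencies,
    freq_gap: float = 0.8,
) -> list[EffectCall]:
    """Shortlist non-synonymous calls divergent between the panels.

    ``frequencies`` maps ``(chrom, pos)`` to ``(freq_dom, freq_wild)``
    (a DataFrame with chrom/pos/freq_dom/freq_wild columns, e.g. from
    ``sweep.allele_frequency_track``, is also accepted).  Calls whose
    populations differ in frequency by at least ``freq_gap`` are returned
    with frequencies attached; ``freq_gap=0`` returns every
    non-synonymous call with known frequencies.
    """
    if hasattr(frequencies, "itertuples"):
        frequencies = {
            (r.chrom, int(r.pos)): (float(r.freq_dom), float(r.freq_wild))
            for r in frequencies.itertuples(index=False)
        }
    out = []
    for call in effect_calls:
        if call.effect != "non-synonymous":
            continue
        freqs = frequencies.get((call.chrom, call.pos))
        if freqs is None:
            continue
        f_dom, f_wild = freqs
        if abs(f_dom - f_wild) >= freq_gap:
            out.append(
                EffectCall(
                    chrom=call.chrom,
                    pos=call.pos,
                    ref=call.ref,
                    alt=call.alt,
                    gene_id=call.gene_id,
                    effect=call.effect,
                    protein_change=call.protein_change,
                    freq_dom=f_dom,
                    freq_wild=f_wild,
                )
            )
    return out
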