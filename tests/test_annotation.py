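"""Coding-effect calls: codon path vs full-protein-diff oracle."""
import numpy as np
import pytest
from Bio.Seq import Seq

from bsasweep import classify_variant, divergent_nonsynonymous
from bsasweep.annotation import EffectCall, ReferenceMismatchError
from bsasweep.variant_io import GeneModel, reverse_complement

# toy gene: CDS "ATG GGT TAA" at 11..19 on a 40 bp chromosome
GENOME = {"c": "N" * 10 + "ATGGGTTAA" + "N" * 21}
GENE = GeneModel("g", "c", "+", [(11, 19)], tx_start=8, tx_end=22)


def _call(pos, ref, alt, models=None, genome=None):
    calls = classify_variant("c", pos, ref, alt, models or [GENE], genome or GENOME)
    assert len(calls) == 1
    return calls[0]


def test_nonsynonymous_g_to_d():
    # codon 2 position 2: GGT -> GAT, glycine -> aspartate
    call = _call(15, "G", "A")
    assert call.effect == "non-synonymous"
    assert call.protein_change == "G2D"


def test_synonymous_third_position():
    call = _call(16, "T", "C")  # GGT -> GGC
    assert call.effect == "synonymous"
    assert call.protein_change == "G2G"


def test_stop_gain_and_stop_loss():
    # codon2 GGA -> TGA: glycine to stop
    genome = {"c": "N" * 10 + "ATGGGATAA" + "N" * 21}
    gene = GeneModel("g", "c", "+", [(11, 19)])
    call = classify_variant("c", 14, "G", "T", [gene], genome)[0]
    assert call.effect == "stop-gain"
    assert call.protein_change == "G2*"
    # codon3 TAA -> CAA: stop to glutamine
    call = _call(17, "T", "C")
    assert call.effect == "stop-loss"
    assert call.protein_change == "*3Q"


def test_intronic_utr_intergenic_and_indels():
    two_exon = GeneModel("g2", "c", "+", [(11, 15), (17, 20)], tx_start=8, tx_end=22)
    assert _call(16, "T", "C", [two_exon]).effect == "intronic"
    assert _call(9, "N", "A").effect == "UTR"
    assert classify_variant("c", 30, "N", "A", [GENE], GENOME)[0].effect == "intergenic"
    assert _call(13, "G", "GATG").effect == "inframe-indel"  # +3 bp
    assert _call(13, "G", "GA").effect == "frameshift"  # +1 bp


def test_reference_mismatch_raises():
    with pytest.raises(ReferenceMismatchError):
        _call(15, "C", "A")


def test_flagged_model_is_skipped():
    bad = GeneModel("bad", "c", "+", [(11, 18)])  # 8 bp CDS, flagged
    calls = classify_variant("c", 15, "G", "A", [bad], GENOME)
    assert calls[0].effect == "intergenic"


def _random_gene(rng):
    """Random 1–2 exon gene on a random genome; returns (model, genome)."""
    n_codons = int(rng.integers(10, 40))
    cds = "ATG" + "".join(rng.choice(list("ACGT"), 3 * (n_codons - 2))) + "TAA"
    strand = rng.choice(["+", "-"])
    genomic = cds if strand == "+" else reverse_complement(cds)
    left = int(rng.integers(5, 20))
    if rng.random() < 0.5:
        split = int(rng.integers(1, len(genomic)))
        intron = "".join(rng.choice(list("ACGT"), int(rng.integers(4, 12))))
        seq = "N" * left + genomic[:split] + intron + genomic[split:] + "N" * 10
        e1 = (left + 1, left + split)
        e2 = (left + split + len(intron) + 1, left + len(genomic) + len(intron))
        model = GeneModel("g", "c", strand, [e1, e2])
    else:
        seq = "N" * left + genomic + "N" * 10
        model = GeneModel("g", "c", strand, [(left + 1, left + len(genomic))])
    return model, {"c": seq}


def _oracle(model, genome, pos, alt):
    """Independent classification by translating the fully mutated CDS."""
    parts = []
    for a, b in model.cds:
        s = genome["c"][a - 1 : b]
        if a <= pos <= b:
            i = pos - a
            s = s[:i] + alt + s[i + 1 :]
        parts.append(s)
    mutated = "".join(parts)
    if model.strand == "-":
        mutated = reverse_complement(mutated)
    ref_cds = []
    for a, b in model.cds:
        ref_cds.append(genome["c"][a - 1 : b])
    ref = "".join(ref_cds)
    if model.strand == "-":
        ref = reverse_complement(ref)
    p_ref = str(Seq(ref).translate())
    p_alt = str(Seq(mutated).translate())
    if p_ref == p_alt:
        return "synonymous"
    diff = [i for i, (x, y) in enumerate(zip(p_ref, p_alt)) if x != y]
    i = diff[0]
    if p_alt[i] == "*":
        return "stop-gain"
    if p_ref[i] == "*":
        return "stop-loss"
    return "non-synonymous"


def test_codon_path_matches_full_protein_oracle():
    """500 random CDS SNPs, both strands, spliced and unspliced genes."""
    rng = np.random.default_rng(99)
    for _ in range(500):
        model, genome = _random_gene(rng)
        cds_positions = [p for a, b in model.cds for p in range(a, b + 1)]
        pos = int(rng.choice(cds_positions))
        ref = genome["c"][pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        calls = classify_variant("c", pos, ref, alt, [model], genome)
        assert len(calls) == 1
        assert calls[0].effect == _oracle(model, genome, pos, alt)
        assert calls[0].effect in (
            "synonymous", "non-synonymous", "stop-gain", "stop-loss"
        )


def test_minus_strand_call_equals_mirrored_plus_strand():
    """Classifying on '-' equals the reverse-complemented '+' construction."""
    rng = np.random.default_rng(5)
    for _ in range(50):
        n_codons = 12
        cds = "ATG" + "".join(rng.choice(list("ACGT"), 3 * (n_codons - 2))) + "TAA"
        plus_genome = {"c": "NNNNN" + cds + "NNNNN"}
        plus = GeneModel("p", "c", "+", [(6, 5 + len(cds))])
        minus_genome = {"c": reverse_complement(plus_genome["c"])}
        minus = GeneModel("m", "c", "-", [(6, 5 + len(cds))])

        off = int(rng.integers(0, len(cds)))
        pos_p = 6 + off
        ref_p = plus_genome["c"][pos_p - 1]
        alt_p = str(rng.choice([b for b in "ACGT" if b != ref_p]))
        pos_m = len(minus_genome["c"]) - pos_p + 1
        ref_m = reverse_complement(ref_p)
        alt_m = reverse_complement(alt_p)

        cp = classify_variant("c", pos_p, ref_p, alt_p, [plus], plus_genome)[0]
        cm = classify_variant("c", pos_m, ref_m, alt_m, [minus], minus_genome)[0]
        assert cp.effect == cm.effect
        assert cp.protein_change == cm.protein_change


def test_divergent_nonsynonymous_shortlist():
    calls = [
        EffectCall("c", 15, "G", "A", "g", "non-synonymous", "G2D"),
        EffectCall("c", 16, "T", "C", "g", "synonymous", "G2G"),
        EffectCall("c", 18, "A", "G", "g", "non-synonymous", "*3W"),
    ]
    freqs = {("c", 15): (0.98, 0.05), ("c", 16): (0.99, 0.01), ("c", 18): (0.6, 0.4)}
    out = divergent_nonsynonymous(calls, freqs, freq_gap=0.8)
    assert [c.pos for c in out] == [15]
    assert out[0].freq_dom == pytest.approx(0.98)
    # degenerate threshold returns every non-synonymous call with known freqs
    out0 = divergent_nonsynonymous(calls, freqs, freq_gap=0.0)
    assert [c.pos for c in out0] == [15, 18]
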