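"""Synthetic backcross bulks and two-population panels with ground truth.

The cross emulated here: a recessive, fully homozygous reference strain
(P50) is crossed to a wild strain fixed for the alternative allele at
every marker; the F1 male is backcrossed to P50 females, so every BC1
individual inherits a constant P50 gamete plus one recombinant F1 gamete
and is either heterozygous or homozygous-P50 at each marker — never
homozygous wild.  A dominant causal locus with configurable penetrance
assigns phenotypes; extreme-phenotype bulks of ~20 larvae are pooled and
"sequenced" by Poisson depths with binomial allele sampling, at depths
matching low-coverage whole-genome pools (~20–37×).

The population panel emulates a resequenced strain collection (a large
domestic panel against a handful of wild strains) carrying one sweep
region: inside it the domestic panel is pushed toward fixation (low
heterozygosity) and shifted in frequency away from the wild panel.
"""
from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sweep import PopulationPanel
from .variant_io import MarkerTable

__all__ = [
    "CrossConfig",
    "PanelConfig",
    "SimTruth",
    "InsufficientSegregantsError",
    "simulate_cross",
    "sample_bulk_counts",
    "simulate_panel",
    "write_fixture",
]

P50 = "P_P50"
WILD = "P_Wild"
BULK_POS = "bulk_pos"  # trait-positive (wild-behavior) bulk
BULK_NEG = "bulk_neg"  # trait-negative (P50-like) bulk


class InsufficientSegregantsError(ValueError):
    """Too few individuals in a phenotype class to fill a bulk."""


@dataclass
class CrossConfig:
    """Parameters of the simulated BC1 mapping cross.

    ``recomb_rate`` is the chromosome's genetic length in Morgans
    (expected crossovers per meiosis).  ``depth_mean`` is the mean pooled
    read depth per marker per bulk; ``parent_depth_mean`` the mean
    per-parent depth.  Defaults mirror a ~200-individual BC1 with bulks
    of 20 sequenced at ~30× and parents at ~21×.
    """

    chrom: str = "chr19"
    chrom_length: int = 20_000_000
    n_markers: int = 2_000
    marker_positions: object = "uniform"  # "uniform" or sorted bp array
    causal_position: int | None = 4_000_000
    recomb_rate: float = 2.0
    n_bc1: int = 200
    bulk_size: int = 20
    penetrance: float = 1.0
    depth_mean: float = 30.0
    parent_depth_mean: float = 21.0
    seed: int = 0
    random_bulks: bool = False

    def __post_init__(self) -> None:
        if self.chrom_length < 1 or self.n_markers < 1 or self.n_bc1 < 1:
            raise ValueError("all counts must be positive")
        if self.bulk_size < 1 or self.bulk_size > self.n_bc1:
            raise ValueError("bulk_size must be in [1, n_bc1]")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must lie in [0, 1]")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be non-negative")
        if self.depth_mean <= 0 or self.parent_depth_mean <= 0:
            raise ValueError("depth means must be positive")
        if self.causal_position is not None and not (
            1 <= self.causal_position <= self.chrom_length
        ):
            raise ValueError("causal_position outside [1, chrom_length]")

    def positions(self) -> np.ndarray:
        if isinstance(self.marker_positions, str):
            if self.marker_positions != "uniform":
                raise ValueError(f"unknown positions spec {self.marker_positions!r}")
            pos = np.unique(
                np.round(np.linspace(1, self.chrom_length, self.n_markers)).astype(
                    np.int64
                )
            )
            return pos
        pos = np.asarray(self.marker_positions, dtype=np.int64)
        if np.any(np.diff(pos) <= 0):
            raise ValueError("marker_positions must be strictly increasing")
        if pos[0] < 1 or pos[-1] > self.chrom_length:
            raise ValueError("marker_positions outside chromosome")
        return pos


@dataclass
class SimTruth:
    """Ground truth of one simulated cross.

    ``bc1_genotypes`` codes hom-ref as 0 and het as 1 (hom-alt cannot
    occur in a backcross to the recessive parent).  ``causal_index`` is
    the marker the causal position snapped to.
    """

    config: CrossConfig
    positions: np.ndarray
    parent_haplotypes: np.ndarray  # (2, n_markers): P50 all-0, wild all-1
    bc1_genotypes: np.ndarray  # (n_bc1, n_markers) uint8
    phenotypes: np.ndarray  # (n_bc1,) bool
    bulk_pos_members: np.ndarray
    bulk_neg_members: np.ndarray
    causal_position: int | None
    causal_index: int | None


def simulate_cross(config: CrossConfig) -> SimTruth:
    """Simulate BC1 genotypes, phenotypes and bulk membership.

    Each individual's wild-derived gamete is produced by a crossover
    process with Poisson(``recomb_rate``) breakpoints placed uniformly on
    the chromosome (no interference); only the F1 gamete recombines, the
    P50 gamete is constant.  Phenotype is assigned from the causal-marker
    genotype with the stated penetrance; bulks are the first
    ``bulk_size`` trait-positive and trait-negative individuals (or a
    random subset with ``random_bulks``).
    """
    rng = np.random.default_rng(config.seed)
    pos = config.positions()
    m = len(pos)

    causal_index = None
    if config.causal_position is not None:
        if not pos[0] <= config.causal_position <= pos[-1]:
            raise ValueError(
                f"causal_position {config.causal_position} outside the marker "
                f"range [{pos[0]}, {pos[-1]}]"
            )
        causal_index = int(np.argmin(np.abs(pos - config.causal_position)))

    geno = np.empty((config.n_bc1, m), dtype=np.uint8)
    n_breaks = rng.poisson(config.recomb_rate, size=config.n_bc1)
    start_allele = rng.integers(0, 2, size=config.n_bc1)
    for i in range(config.n_bc1):
        if n_breaks[i] == 0:
            geno[i] = start_allele[i]
            continue
        breaks = np.sort(rng.uniform(0, config.chrom_length, size=n_breaks[i]))
        parity = np.searchsorted(breaks, pos) % 2
        geno[i] = (start_allele[i] + parity) % 2

    if causal_index is not None:
        carrier = geno[:, causal_index] == 1
        phen = carrier & (rng.random(config.n_bc1) < config.penetrance)
    else:
        phen = np.zeros(config.n_bc1, dtype=bool)

    pos_idx = np.flatnonzero(phen)
    neg_idx = np.flatnonzero(~phen)
    if len(pos_idx) < config.bulk_size or len(neg_idx) < config.bulk_size:
        raise InsufficientSegregantsError(
            f"insufficient segregants: {len(pos_idx)} trait-positive / "
            f"{len(neg_idx)} trait-negative, need {config.bulk_size} each"
        )
    if config.random_bulks:
        bulk_pos = rng.choice(pos_idx, size=config.bulk_size, replace=False)
        bulk_neg = rng.choice(neg_idx, size=config.bulk_size, replace=False)
        bulk_pos.sort()
        bulk_neg.sort()
    else:
        bulk_pos = pos_idx[: config.bulk_size]
        bulk_neg = neg_idx[: config.bulk_size]

    return SimTruth(
        config=config,
        positions=pos,
        parent_haplotypes=np.vstack(
            [np.zeros(m, dtype=np.uint8), np.ones(m, dtype=np.uint8)]
        ),
        bc1_genotypes=geno,
        phenotypes=phen,
        bulk_pos_members=bulk_pos,
        bulk_neg_members=bulk_neg,
        causal_position=config.causal_position,
        causal_index=causal_index,
    )


def sample_bulk_counts(truth: SimTruth, config: CrossConfig | None = None) -> MarkerTable:
    """Draw pooled sequencing counts for parents and both bulks.

    At each marker the true wild-allele frequency in a bulk is
    (heterozygote members × 0.5) / bulk size; total depth is
    Poisson(``depth_mean``), floored at 1, and the non-reference count is
    Binomial(depth, frequency).  Parents are sequenced error-free at
    frequency 0 (P50) and 1 (wild) with Poisson(``parent_depth_mean``)
    depth.  Counts are returned as an already-oriented
    :class:`~bsasweep.variant_io.MarkerTable`.
    """
    config = config or truth.config
    # Independent stream from the cross: offset the seed so genotypes and
    # read sampling never share draws.
    rng = np.random.default_rng((config.seed + 1_000_003) % (2**31))
    m = len(truth.positions)

    data = {
        "chrom": np.repeat(config.chrom, m),
        "pos": truth.positions,
        "variant_type": np.repeat("SNP", m),
    }
    for sample, f in ((P50, 0.0), (WILD, 1.0)):
        depth = np.maximum(rng.poisson(config.parent_depth_mean, size=m), 1)
        nonref = rng.binomial(depth, f)
        data[f"{sample}_ref"] = depth - nonref
        data[f"{sample}_nonref"] = nonref
    for sample, members in (
        (BULK_POS, truth.bulk_pos_members),
        (BULK_NEG, truth.bulk_neg_members),
    ):
        het = truth.bc1_genotypes[members].sum(axis=0)
        f = 0.5 * het / len(members)
        depth = np.maximum(rng.poisson(config.depth_mean, size=m), 1)
        nonref = rng.binomial(depth, f)
        data[f"{sample}_ref"] = depth - nonref
        data[f"{sample}_nonref"] = nonref

    return MarkerTable(
        df=pd.DataFrame(data),
        parents=(P50, WILD),
        bulks=(BULK_POS, BULK_NEG),
        filters={"source": "simulated", "seed": config.seed},
    )


@dataclass
class PanelConfig:
    """Parameters of the two-population panel simulator.

    Defaults emulate a resequenced collection of 137 domestic and 7 wild
    haploid strain genomes over a 5 Mb candidate region carrying one
    sweep at 3.7–4.0 Mb.  Heterozygosities are per-site expected values
    (2p(1−p), bounded by 0.5 for biallelic sites).
    """

    chrom: str = "chr19"
    chrom_length: int = 5_000_000
    n_pop1: int = 137  # "domestic" haploid samples
    n_pop2: int = 7  # "wild" haploid samples
    n_sites: int = 5_000
    sweep_interval: tuple[int, int] | None = (3_700_000, 4_000_000)
    baseline_diversity: float = 0.2
    sweep_diversity_pop1: float = 0.01
    divergence_boost: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pop1 < 2 or self.n_pop2 < 2:
            raise ValueError("each population needs at least 2 haploid samples")
        if self.n_sites < 1 or self.chrom_length < 1:
            raise ValueError("n_sites and chrom_length must be positive")
        for h in (self.baseline_diversity, self.sweep_diversity_pop1):
            if not 0.0 <= h <= 0.5:
                raise ValueError("per-site heterozygosity must lie in [0, 0.5]")
        if self.sweep_interval is not None:
            lo, hi = self.sweep_interval
            if not (1 <= lo < hi <= self.chrom_length):
                raise ValueError("sweep_interval outside chromosome")
            if self.sweep_diversity_pop1 > self.baseline_diversity:
                warnings.warn(
                    "sweep diversity exceeds baseline diversity; the 'sweep' "
                    "will not depress pop1 heterozygosity",
                    stacklevel=2,
                )


def _freq_for_het(h: float) -> float:
    """Minor-allele frequency whose expected heterozygosity 2p(1-p) = h."""
    return 0.5 * (1.0 - float(np.sqrt(max(0.0, 1.0 - 2.0 * h))))


def simulate_panel(config: PanelConfig) -> PopulationPanel:
    """Draw a two-population haploid panel with one optional sweep.

    Outside the sweep interval both populations share a common per-site
    frequency with expected heterozygosity ``baseline_diversity`` (allele
    orientation randomized per site).  Inside it the pop1 non-reference
    frequency is pushed toward fixation (heterozygosity
    ``sweep_diversity_pop1``) and pop2 is shifted down by
    ``divergence_boost``.  Genotypes are independent Bernoulli draws per
    haploid sample; the truth interval is retained on the panel.
    """
    rng = np.random.default_rng(config.seed)
    positions = np.sort(
        rng.choice(
            np.arange(1, config.chrom_length + 1),
            size=min(config.n_sites, config.chrom_length),
            replace=False,
        )
    )
    m = len(positions)

    base_minor = _freq_for_het(config.baseline_diversity)
    orient = rng.integers(0, 2, size=m)
    p_common = np.where(orient == 1, 1.0 - base_minor, base_minor)
    p1 = p_common.copy()
    p2 = p_common.copy()

    if config.sweep_interval is not None:
        lo, hi = config.sweep_interval
        inside = (positions >= lo) & (positions <= hi)
        sweep_minor = _freq_for_het(config.sweep_diversity_pop1)
        p1[inside] = 1.0 - sweep_minor  # non-reference allele near-fixed in pop1
        p2[inside] = np.clip(p1[inside] - config.divergence_boost, 0.0, 1.0)

    pop1 = rng.binomial(1, p1[:, None], size=(m, config.n_pop1)).astype(np.int8)
    pop2 = rng.binomial(1, p2[:, None], size=(m, config.n_pop2)).astype(np.int8)
    return PopulationPanel(
        chrom=config.chrom,
        positions=positions,
        pop1=pop1,
        pop2=pop2,
        chrom_length=config.chrom_length,
        sweep_interval=config.sweep_interval,
    )


# ---------------------------------------------------------------------------
# Fixture output


def _write_vcf(table: MarkerTable, truth: SimTruth, path: Path) -> None:
    """Minimal VCF 4.2 with GT and AD for parents and bulks.

    Synthetic alleles: REF 'A' (the P50 allele), ALT 'T'.  Bulks are
    pooled, so their GT is './.' while AD carries the pooled counts.
    """
    p50, wild = table.parents
    samples = list(table.samples)
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={truth.config.chrom},length={truth.config.chrom_length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    gts = {p50: "0/0", wild: "1/1"}
    for row in table.df.itertuples(index=False):
        fields = [row.chrom, str(row.pos), ".", "A", "T", ".", "PASS", ".", "GT:AD"]
        for s in samples:
            ref = getattr(row, f"{s}_ref")
            nonref = getattr(row, f"{s}_nonref")
            fields.append(f"{gts.get(s, './.')}:{ref},{nonref}")
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


def write_fixture(
    truth: SimTruth,
    counts: MarkerTable,
    panel: PopulationPanel | None,
    out_dir: str | os.PathLike,
) -> dict[str, Path]:
    """Write the simulated dataset as plain-text files.

    Produces ``markers.vcf`` (GT + AD per sample), ``panel.tsv`` (sites ×
    haploid samples of {0,1}) when a panel is given, and ``truth.json``.
    The VCF round-trips through ``variant_io.read_variants`` /
    ``select_markers`` without loss.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["vcf"] = out / "markers.vcf"
    _write_vcf(counts, truth, paths["vcf"])

    if panel is not None:
        paths["panel"] = out / "panel.tsv"
        panel.to_frame().to_csv(paths["panel"], sep="\t", index=False, na_rep="NA")

    paths["truth"] = out / "truth.json"
    cfg = truth.config
    paths["truth"].write_text(
        json.dumps(
            {
                "chrom": cfg.chrom,
                "chrom_length": cfg.chrom_length,
                "causal_position": truth.causal_position,
                "causal_marker_position": (
                    int(truth.positions[truth.causal_index])
                    if truth.causal_index is not None
                    else None
                ),
                "recomb_rate": cfg.recomb_rate,
                "n_bc1": cfg.n_bc1,
                "bulk_size": cfg.bulk_size,
                "penetrance": cfg.penetrance,
                "seed": cfg.seed,
                "bulk_pos_members": truth.bulk_pos_members.tolist(),
                "bulk_neg_members": truth.bulk_neg_members.tolist(),
                "phenotypes": truth.phenotypes.astype(int).tolist(),
                "panel_sweep_interval": (
                    list(panel.sweep_interval)
                    if panel is not None and panel.sweep_interval
                    else None
                ),
            },
            indent=1,
        )
    )
    return paths
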