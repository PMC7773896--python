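# Methods

## The mapping model

The design assumed throughout is a first backcross (BC1) between a
fully homozygous recessive reference strain (called P50 after the
domestic silkworm strain that motivated the package) and an F1 carrying
one wild-derived haplotype. Every BC1 individual inherits a constant
P50 gamete plus one recombinant F1 gamete, so each marker genotype is
either heterozygous or homozygous-P50 — never homozygous-wild — and a
fully-penetrant dominant locus segregates 1:1. Markers are sites where
the two parents are homozygous for different alleles; all counts are
re-oriented so "reference" means the P50 allele, regardless of which
allele the assembly happens to carry.

For a bulk of pooled individuals, the per-marker index is the
non-reference read fraction. With perfect extreme bulks at a dominant
locus, the trait-positive bulk is all heterozygotes (expected index
0.5) and the trait-negative bulk all homozygotes (expected 0), giving
E[Δ] = 0.5 at the causal marker; away from it the expectation decays as
0.5·(1 − 2r) with recombination fraction r. Window means (default 1 Mb
window, 10 kb step, anchored at position 1, half-open intervals, last
partial window kept) are unweighted over the markers present; empty
windows are missing, never zero, and missing windows are excluded from
all exceedance and region logic.

## The confidence band

The published QTL-seq workflow quotes "1,000 permutation tests with a
95% confidence level" without defining the permuted unit; reads in a
pool carry no individual labels, so a literal label permutation does
not exist. The band here is the standard parametric interpretation:
under the no-linkage null a random BC1 bulk contains heterozygotes with
probability ½, so each bulk's expected non-reference read fraction is
0.25. Every replicate redraws each marker's two bulk counts as
Binomial(observed depth, 0.25) independently, recomputes the windowed
Δ, and the band is the per-window empirical α/2 and 1−α/2 quantiles
over replicates (`null_freq` is configurable for other designs). The
band is per-window — it therefore widens where marker count or depth is
low — and reproducible given a seed.

Region calling offers two modes. "Strict" takes maximal runs of
windows beyond the band (upper tail by default), merging runs separated
by less than one window width. "Peak" takes the top `top_q` fraction of
windows by Δ (default 0.005, ties broken leftmost) and merges them the
same way; this is the pragmatic call when a clear peak fails to clear
the band, which is the common outcome for behavioral traits with
imperfect phenotyping. Region sets from independent bulk pairs can be
intersected; the intersection of a [3,5] Mb and a [1,5] Mb call is the
[3,5] Mb interval.

## Sweep statistics

Nucleotide diversity per window is Σ_sites 2p̂(1−p̂)·n/(n−1) divided by
the window length in base pairs (not callable sites — stated in output
metadata), with n the non-missing haploid calls at the site; sites with
fewer than two calls in a population are skipped. Fst uses Hudson's
estimator as a ratio of averages,

    Fst(window) = Σ N_s / Σ D_s,
    N_s = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1),
    D_s = p1(1−p2) + p2(1−p1),

chosen because the within-population variance correction matters when
one panel is very small (seven wild strains against 137 domestic ones);
a Weir–Cockerham haploid ANOVA form is available as an option. Reported
window values are clamped to [0,1] with the raw ratio retained. The
top-quantile cutoff (default top 5%) is computed over the supplied
profiles, i.e. the chromosome set actually analyzed, not a genome-wide
constant. A window is a sweep candidate when it passes the cutoff *and*
its domestic π is below its wild π; genes are reported when their span
intersects a flagged window. Sweep scan granularity defaults to 10 kb
windows with a 5 kb step — a display-scale choice, not a value carried
over from any published scan.

## Effect annotation

Gene models are single-isoform CDS interval lists (1-based inclusive,
genome order); minus-strand models are reverse-complemented on
extraction, and models whose CDS length is not a multiple of 3 are
flagged and excluded from calls. A CDS SNP is classified by mutating
its codon and comparing amino acids; residue numbering is 1-based from
the initiator methionine and stops translate as `*`, so a
glycine→aspartate change at residue 115 reports as `G115D`. Indels are
frameshift when the length change is not a multiple of 3, in-frame
otherwise (with a protein-level diff when the edit sits inside one CDS
interval). Variants between CDS intervals are intronic; within the
transcript span but outside the CDS span, UTR; elsewhere, intergenic.
All overlapping transcripts yield calls — no canonical-transcript
ranking. The test suite checks the codon fast path against an
independent oracle that translates the entire mutated CDS.

## Expression comparisons

Heatmap normalization is the per-gene z-score with sample standard
deviation (ddof 1); constant rows return zeros and are flagged.
Between-group testing rescales each sample's FPKM by reference
depth / library depth (reference = mean depth by default) and applies
the classical equal-variance two-sample Student's t-test per gene,
two-sided, with no multiple-testing correction — matching the workflow
this package reimplements, which applied none. Degenerate inputs are
explicit: fewer than two replicates gives a missing p-value; zero
variance in both groups with equal means gives t = 0, p = 1, flagged.

## The synthetic-data generator

The generator produces the *statistical structure* the analysis
assumes, not sequence-level realism. Crossovers on the F1 gamete are a
Poisson count (default 2 expected crossovers per chromosome — a free
parameter, not a claim about any species' genetic map) with uniform
breakpoint positions and no interference; only the F1 gamete
recombines, the P50 gamete is constant. Phenotypes follow the
causal-marker genotype with configurable penetrance (default 1.0); the
causal position snaps to the nearest marker. Bulks are the first k
individuals of each phenotype class for reproducibility (random
sampling behind a flag). Pooled sequencing draws a Poisson depth per
marker per bulk (default mean 30; parents 21) floored at one read, then
a binomial non-reference count at the bulk's true allele frequency —
there is no base-error model, since the statistics operate on counts
after upstream genotype filtering. Default cross scale: 2,000 markers
on a 20 Mb chromosome, 200 BC1 individuals, bulks of 20, causal locus
at 4.0 Mb.

The panel generator draws per-site frequencies deterministically from
the target heterozygosity (2p(1−p) inverted for p, allele orientation
randomized per site) rather than from a neutral site-frequency
spectrum; outside the sweep both populations share the frequency,
inside it the domestic panel is pushed toward fixation (default
heterozygosity 0.01 against a 0.2 baseline) and the wild panel is
offset by a divergence shift (default 0.8). Defaults: 137 + 7 haploid
samples, 5,000 sites on 5 Mb, sweep at 3.7–4.0 Mb. Consequently
passing tests demonstrate correct behavior of the estimators under the
assumed sampling model — binomial reads, Bernoulli haploid calls,
independent sites outside the sweep — and say nothing about linkage
disequilibrium structure, allele-frequency spectra, sequencing error or
mapping bias in real data.

Fixtures are plain text: a VCF 4.2 with GT and AD per sample (bulks
carry `./.` genotypes with pooled AD), a sites × haploid-samples panel
matrix, and a truth JSON; the VCF round-trips losslessly through the
reader and marker selector.

## Numerical and design choices

- All randomness flows from one integer seed per generator through
  NumPy's `default_rng`; the count sampler offsets the cross seed so
  genotype and read draws never share a stream. Identical seed and
  configuration give byte-identical fixtures.
- The bulk-depth exclusion rule is read literally: a site is dropped
  only when *both* bulks are below the depth threshold (default 7) or
  when either bulk has no coverage at all; a single shallow bulk is
  retained.
- Parent homozygosity comes from the genotype call, not inferred from
  counts; sites with a missing or heterozygous parent call are
  excluded.
- Multiallelic sites are skipped by default (the index is defined for
  two allele classes).
- Zero-depth sites yield a missing index, contributing nothing to
  windows; Fst windows whose denominator sums to zero are missing.
- Δ sign convention: trait-positive bulk minus trait-negative bulk, so
  causal linkage is positive; exceedance supports one- or two-sided
  calling (two-sided for calibration, upper tail for region calls).
- SNPs and InDels flow through the same statistic jointly; the marker
  table keeps the type column so they can be separated.
- Coordinates are 1-based inclusive at every file boundary; window
  intervals are half-open internally and exported BED-style.

## Problem sizes used by the test suite

The calibration check uses 2,000 null markers on 20 Mb with disjoint
10 kb windows (window = step), giving ~1,250 marker-bearing,
independent windows so the 5% exceedance fraction has a standard error
near 0.006; heavily overlapping display grids (1 Mb / 10 kb) are
visually useful but carry only ~20 independent windows per chromosome
and cannot estimate calibration tightly. Recovery experiments run 50
seeded replicates at the default cross and panel scales; the Δ-index
expectation is averaged over 200 replicate crosses at 10,000× pooled
depth, where binomial noise is negligible.

## Known limitations

- No coalescent or LD-aware panel simulation; sites are independent
  given their frequencies.
- No multi-chromosome genetic maps; profiles are per-chromosome and
  multi-chromosome inputs are looped externally (as the CLI does).
- InDels are treated as biallelic markers identical to SNPs.
- Splice-site effects, multi-transcript consequence ranking and
  cross-species selection tests are out of scope.
- The t-test utilities assume FPKM inputs; quantification from reads is
  upstream of this package.
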