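# Methods

## Scope and data model

The package analyses haploid segregants of a biparental yeast cross from
genotype likelihoods and binned depth tracks onward; alignment and raw
variant calling are upstream and out of scope. Coordinates are 0-based
half-open internally, 1-based on VCF emission, BED-native on BED I/O.
Genotype calls live in an `int8` matrix over {P1, P2, HET, MISSING}; HET in
a haploid is never used for mapping (it is uninformative to the HMMs) but
is kept as a QC signal, since disomic chromosomes produce het-like
likelihoods.

## Synthetic-data generator

The generator defines the study conditions; its defaults are fixed and the
tests are statements about data generated under them.

| parameter | default | meaning |
|---|---|---|
| `chrom_lengths` | 16 chromosomes, 12,071,326 bp | S288c-like karyotype |
| `marker_density` | 1/190 per bp | ~63.5k parental-informative SNPs |
| `xo_per_genome` | 50 | expected crossovers per segregant (5000 cM map) |
| `error_prob` | 0.01 | symmetric genotype miscall probability |
| `call_rate` | 0.886 | fraction of markers confidently called |
| `depth_mean` | 30 | haploid mean coverage (x) |
| `gc_bias` | quadratic, center 0.45, curvature 2.5, floor 0.1 | relative depth vs GC |

Mechanics: marker counts are Binomial(L, density) with uniform distinct
positions; crossover counts per chromosome are Poisson with mean
proportional to physical length, positions uniform or drawn from a
supplied intensity track (used to emulate hotspot structure, including a
depletion ring around hotspot centers); the starting parent is a fair
coin. Likelihoods give the favoured genotype PL 0 and the other a uniform
integer in [30, 90]; a miscall (probability `error_prob`) swaps the
labels; an uncalled site (probability 1 − `call_rate`) has equal PLs and
decodes to MISSING. Binned coverage is Poisson(depth_mean × CN ×
gc_bias(GC)) per bin; bin GC fractions follow an AR(1) wander (mean 0.38,
sd 0.06, lag-1 correlation 0.9) resembling the scale of real yeast GC
variation. Allele counts put all reads (minus sequencing error, default
0.002) on the carried allele; a meiotic gain makes every site a 50/50
binomial at doubled depth; a mitotic gain scales depth by 1 + cell
fraction without changing the per-site allele, because the duplicated copy
is the segregant's own haplotype.

What the generator does **not** emulate: read-level data and base
qualities, mappability gaps and repeats, PCR duplicates, segregation
distortion, crossover interference and obligate chiasmata, gene
conversion, chromosome-12 rDNA copy-number noise, and mitochondria.
Passing recovery tests therefore shows the estimators are correct under
the stated stochastic model, not that real-data artifacts beyond that
model are handled.

The crossover-count distribution across segregants is modelled as Poisson;
only the mean is anchored in the design, and no interference is imposed.
This is the simplest model consistent with the target statistic and is the
main distributional assumption a user should be aware of.

Determinism: every stage derives an independent substream from the single
seed via `SeedSequence(seed, spawn_key=(stage, index))`, with one substream
per segregant, so reruns are byte-identical and enlarging a cohort never
changes previously generated segregants.

## Genotyping

Informative sites are exactly those hom-ref in parent 1 and hom-variant in
parent 2; sites missing or heterozygous in either parent are dropped. The
PL caller requires a gap of `min_gap` = 20 phred (ties and small gaps give
MISSING); the threshold is a confidence floor chosen to make miscalls the
dominant error mode rather than borderline calls. The allele-frequency
filter uses the closed interval [0.3, 0.7] (boundary values are kept).
Imputation is a per-segregant, per-chromosome two-state forward–backward
with emission error `error_prob` and Haldane transition fractions from
either a genetic map or a constant intensity of 50/12,071,326 Morgans per
bp; only MISSING entries are filled (posterior-max), existing calls are
never altered, and chromosomes with no calls stay missing. This imputer is
a deliberate stand-in for haplotype-cluster imputers (e.g. Beagle): in a
biparental haploid cross the hidden state really is binary parental
origin, so the two-state chain is the exact model rather than an
approximation. An optional linkage filter drops sites that disagree with
both flanking columns in >10% of jointly called segregants.

## Genetic-map estimation

`GeneticMapModel.fit()` runs per-chromosome EM on the two-state
parental-origin HMM with per-interval recombination fractions and fixed
symmetric emission error (default 0.01, matching the generator's miscall
rate). Initialization is the moment estimator r = (p − 2e(1−e))/(1−2e)²
applied to pairwise mismatch fractions of adjacent called markers, which
puts EM close to the optimum; convergence is declared when the
log-likelihood changes by less than `tol` (relative, default 1e-5) with a
`maxit` = 1000 cap. The log-likelihood is asserted non-decreasing every
iteration. r is clipped to [1e-6, 0.5 − 1e-6]; intervals adjacent to
markers with fewer than two informative calls are flagged and take r
interpolated from their identifiable neighbours. Haldane is the default
mapping function (no interference, consistent with the Poisson crossover
model); Kosambi is available. cM positions between markers are
interpolated linearly in bp.

Map estimation uses un-imputed calls; imputation only feeds completeness
reporting. Imputed calls would violate the HMM's independent-error
assumption (imputation errors are correlated along the chain).

## Cleaning and crossover counting

Cleaning masks (to MISSING, never flips) every interior run of ≤ `maxmark`
= 2 consecutive same-parent calls flanked on both sides by the opposite
parent when the genetic span between the flanking calls is ≤ `maxdist` =
2.5 cM, in a single pass. Crossovers are counted as adjacent
opposite-parent pairs in the missing-compressed sequence; events at
chromosome ends (before the first or after the last call) are not
countable and terminal runs are not cleanable, which leaves a small
residual inflation (~0.3 events/genome at default error rates). Crossover
events are located between the last call before and the first call after
each switch, with the bp midpoint as the point estimate.

## Rate bins and comparisons

The shared-SNP partition is greedy left-to-right: a bin closes at the
first SNP giving span ≥ 2000 bp, or at the 3000 bp boundary if no SNP
arrives; a terminal remainder < 2000 bp is merged into the previous bin
and flagged, and a chromosome shorter than 2000 bp becomes one flagged
bin. Rates are ΔcM/Δbp with cM interpolated at bin edges, normalized so
the dataset mean is exactly 1. Chromosome-scale comparison aggregates
total cM over total bp per chromosome (equivalently the span-weighted mean
of bin rates) before correlating — not the unweighted mean of bin rates —
which is what "chromosome-wide" rate means physically. Correlation
p-values use the standard t transform and are reported, never used for
gating. Hotspot profiles histogram |event midpoint − nearest center| up to
`max_dist` with fixed-width bins.

## Coverage, GC correction, aneuploidy

Depth density uses a fixed absolute KDE bandwidth of 0.1; breadth(t) is
the fraction of positions at depth ≥ t. Binned tracks flag bins with <50%
of bases covered at ≥1x (exactly 50% is retained — "less than" is read
literally); excluded bins are invisible to the LOESS fit and to CN
medians. The GC curve is a local-linear LOESS (statsmodels `lowess`,
span 0.3) of bin depth on GC; correction multiplies each bin by
global-median/expected-at-its-GC, so the corrected global median equals
the observed one and correction is idempotent to within noise. GC values
outside the fitted support take the nearest boundary value and are
counted. Copy number is ploidy × chromosome-median over genome-median of
corrected depth — medians for robustness to the aneuploid chromosome
itself and rDNA-like bins; mitochondrial bins are excluded from the
baseline; the estimate is invariant to global depth rescaling.

The chromosome allele fraction is the mean per-site **major**-allele read
fraction (folded per site). Folding is what keeps the statistic meaningful
on a recombinant chromosome: a mitotic gain duplicates the segregant's own
mosaic haplotype, so any unfolded or pooled parent-oriented fraction would
mix P1 and P2 segments and drift toward 0.5 for euploid and mitotic
chromosomes alike. The price is a finite-depth bias at balanced sites:
E[max(X, d−X)]/d ≈ 0.573 at depth 30 and ≈ 0.551 at the doubled depth of a
disomic chromosome, approaching 0.5 only as d → ∞. The meiotic band
|af − 0.5| ≤ α = 0.1 is wide enough to absorb this bias with margin at
30x; tests check the statistic against the exact binomial expectation
rather than against 0.5.

Classification thresholds (all configurable): δ = 0.2 around CN 2,
α = 0.1 around allele fraction 0.5, `cn_gain_min` = 1.15 as the floor
separating Poisson depth noise from real sub-clonal gains (cell fraction
≳ 0.15 at 30x), `hom_min` = 0.9 for homozygosity, and ≥10 contiguous
gained 10 kb bins (100 kb) for a partial duplication. Decision order:
partial duplication is only called when the whole-chromosome CN is below
`cn_gain_min`; meiotic requires CN ≈ 2 **and** balance; homozygous gains
classify as mitotic up to CN < 2 + δ (a near-clonal post-meiotic
duplication is still a mitotic event — the homozygous/balanced bands are
disjoint so this cannot collide with the meiotic rule); CN ≥ 2 + δ with
homozygosity is internally inconsistent and reported as `unresolved`
rather than forced into a class. Losses are out of scope (a haploid
monosomy is lethal).

## Problem sizes and numerical notes

The acceptance run uses the full design: 720 segregants × ~63k markers for
crossover and map recovery (EM converges in ~10 iterations per chromosome
from the moment initializer; forward–backward is vectorized across
segregants in scaled form, so no underflow at 8k-marker chromosomes), 1216
ten-kb bins for GC work, a 160-sample cohort for classification, and a
500 kb hotspot chromosome at 1/50 bp marker density so that event
midpoints (median marker spacing 50 bp) resolve the 100 nt depletion ring.
Unit tests run the same machinery on a two-chromosome 1.2 Mb genome that
keeps the real per-bp crossover intensity and marker density, so genetic
spans per interval match the full-scale setting.

## Known limitations

- No interference model; map functions other than Haldane/Kosambi are not
  provided.
- Cleaning cannot see terminal-run artifacts, leaving a small upward bias
  in crossover counts (quantified above and visible in small cohorts).
- The bin/chromosome-scale map correlations printed for the real published
  datasets require those datasets; `compare_maps` is validated on
  synthetic twin maps (perfect, independent, and noise-attenuated cases)
  instead.
- Breakpoint-precise CNV segmentation is out of scope; partial
  duplications are located at 10 kb bin resolution.
- The demultiplexer is nearest-neighbour only; with the distance-3 design
  the 1-mismatch cap is the largest radius with guaranteed unique decoding.
- Under the coarse per-bin Poisson(30) coverage model, the median copy
  number of the smallest chromosomes (chrI has only 23 ten-kb bins) has a
  standard error near 0.05, so `cn_gain_min` = 1.15 sits at roughly 3σ and
  a euploid false-call rate of ~1–2% per cohort is expected on those
  chromosomes. Raising the threshold would trade this against sensitivity
  to sub-clonal gains with cell fractions near 0.15; the default keeps the
  stated sensitivity target.
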