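# sporemap

Downstream genotype analysis for large haploid yeast crosses sequenced at
~30x: genotype calling and filtering, meiotic recombination mapping and
crossover counting, recombination-rate binning and map comparison, and
GC-corrected coverage analysis with meiotic/mitotic aneuploidy
classification. A synthetic-data generator reproduces the statistical
structure of such an experiment, so every stage is testable end to end
without any sequencing data.

## Who this is for

Labs that sporulate a diploid hybrid of two divergent *S. cerevisiae*
strains (e.g. S288c x SK1), sequence hundreds of haploid segregants with
inline 6 bp barcodes, and want per-segregant crossover landscapes and
chromosome copy-number calls from the resulting genotype likelihoods and
depth tracks. The pipeline starts downstream of alignment and variant
calling: its inputs are PL-style likelihoods (VCF or matrices), binned
depth and GC tracks, and barcode lists.

## The model

**Genotyping.** At sites that are homozygous-reference in parent 1 and
homozygous-variant in parent 2, each segregant is called from its
phred-scaled likelihood pair: the parent with the smaller PL wins when the
gap is at least `min_gap` (default 20 phred). Sites whose cohort allele
frequency leaves [0.3, 0.7] are dropped — in a two-parent cross the
expectation is 0.5, and outliers flag mismapping. Remaining gaps can be
filled by a two-state forward–backward imputer whose transition
probabilities are Haldane recombination fractions of the inter-marker
distances.

**Genetic map.** Per chromosome, parental origin along a segregant is a
two-state Markov chain observed through a symmetric miscall channel with
error probability *e*. Each inter-marker interval *j* has its own
recombination fraction *r_j*, estimated by EM (forward–backward E-step over
all segregants, M-step *r_j* = mean posterior switch probability; the
log-likelihood is checked to be non-decreasing). Map distance follows
Haldane, *d* = −50 ln(1 − 2r) cM (Kosambi optional). Genotyping artifacts
that mimic tight double crossovers — runs of ≤ `maxmark` (2) calls flanked
by the opposite parent within `maxdist` (2.5) cM — are masked before
crossovers are counted as parental switches in the missing-compressed call
sequence.

**Rates and comparisons.** The genome is partitioned on shared SNPs into
non-overlapping 2–3 kb bins; the rate per bin is ΔcM/Δbp, normalized to
dataset mean 1; maps are compared by Pearson correlation per bin or per
chromosome (total cM / total bp). Crossover midpoints can be profiled by
distance to DSB-hotspot centers.

**Copy number.** Binned depth is LOESS-detrended against GC fraction
(span 0.3); per-chromosome copy number is the chromosome's median corrected
depth over the genome median. An extra chromosome with both parental
haplotypes at allele fraction 0.5 and CN ≈ 2 is a meiosis-I
missegregation; a homozygous gain with 1 < CN < 2 is a post-meiotic
(mitotic) duplication present in a subset of cells; contiguous gained bin
runs below a whole-chromosome gain are partial duplications.

## Worked example

```python
import sporemap as sp
from sporemap import simulate as sim, genotyping as gt, recomb

cfg = sp.SimConfig(seed=7)                      # 16 chromosomes, ~12.1 Mb
markers = sim.simulate_markers(cfg)             # ~63k informative SNPs
truth, _ = sim.simulate_cross(markers, 96, cfg) # 96 recombinant segregants
pl1, pl2 = sim.simulate_likelihoods(truth, cfg)

calls = gt.call_genotypes(pl1, pl2, min_gap=20)
matrix = sp.GenotypeMatrix(truth.samples, markers, calls)
matrix, report = gt.allele_frequency_filter(matrix, lo=0.3, hi=0.7)
print(f"markers kept: {report.n_kept}/{report.n_input}")
print(f"mean call rate: {gt.completeness(matrix).mean():.3f}")

res = sp.GeneticMapModel(matrix, error_prob=0.01).fit(maxit=1000)
cleaned = recomb.clean_genotypes(matrix, res.genetic_map, maxdist=2.5, maxmark=2)
xo = recomb.count_crossovers(cleaned)
print(f"total map length: {res.total_length_cm():.0f} cM")
print(f"mean crossovers/segregant: {xo.mean():.1f} "
      f"(uncleaned: {recomb.count_crossovers(matrix).mean():.0f})")
```

prints

```
markers kept: 63689/63691
mean call rate: 0.886
total map length: 5254 cM
mean crossovers/segregant: 53.9 (uncleaned: 1171)
```

The generator was configured for 50 crossovers per genome (a 5000 cM map)
with a 1% miscall rate and 88.6% call rate. Without cleaning, miscalls
masquerade as ~1100 tight double crossovers per segregant; cleaning
recovers the true scale. At 96 segregants a few percent of residual
inflation remains; at the full design size of 720 segregants the estimates
land within a fraction of a percent (see the acceptance run below).

The same stages are available from a shell via the `sporemap` CLI
(`simulate`, `demux`, `genotype`, `map`, `rates`, `compare`, `hotspots`,
`aneuploidy`, and `run` for the whole pipeline driven by a YAML config).

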