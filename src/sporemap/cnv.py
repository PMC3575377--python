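"""Coverage QC, GC-bias correction, and aneuploidy classification.

Sequencing depth depends smoothly on window GC content; the dependence is
modelled by LOESS (locally weighted regression) of binned mean depth on GC
fraction and divided out before copy number is read off binned coverage.
Per-chromosome copy number is the ratio of the chromosome's median corrected
depth to the genome-wide median (haploid ploidy 1); the parental allele
fraction at informative sites then separates the two routes to an extra
chromosome: a meiosis-I missegregation puts both parental homologs in the
spore (CN 2, alleles 50/50), while a post-meiotic (mitotic) duplication of
the spore's own recombinant chromosome in a sub-population of cells gives
1 < CN < 2 with homozygous calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import AneuploidyCall, CoverageTrack

# ---------------------------------------------------------------------------
# depth distribution and binning


@dataclass
class DepthDistribution:
    grid: np.ndarray
    density: np.ndarray
    breadth: dict[float, float]


def depth_distribution(
    per_base_depths: np.ndarray,
    bandwidth: float = 0.1,
    thresholds: tuple[float, ...] = (1.0, 10.0),
) -> DepthDistribution:
    """Kernel density of per-base depth plus breadth-of-coverage numbers.

    ``breadth[t]`` is the fraction of positions covered at depth >= t. The
    KDE uses a fixed (absolute) gaussian bandwidth, matching how depth
    densities are usually drawn for coverage QC.
    """
    d = np.asarray(per_base_depths, dtype=float)
    kde = sm.nonparametric.KDEUnivariate(d)
    kde.fit(bw=bandwidth, fft=True, gridsize=1024)
    breadth = {float(t): float((d >= t).mean()) for t in thresholds}
    return DepthDistribution(np.asarray(kde.support), np.asarray(kde.density), breadth)


def bin_coverage(
    per_base_depths: dict[str, np.ndarray], bin_size: int, sample: str = "sample"
) -> CoverageTrack:
    """Mean depth over a fixed non-overlapping tiling of each chromosome.

    Bins with fewer than half their bases covered by at least one read are
    flagged ``excluded`` (kept in the table, ignored by downstream fits).
    """
    rows = []
    for chrom, depths in per_base_depths.items():
        depths = np.asarray(depths, dtype=float)
        length = len(depths)
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        for s in starts:
            chunk = depths[s : s + bin_size]
            frac = float((chunk >= 1).mean())
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(s),
                    "end": int(min(s + bin_size, length)),
                    "frac_covered": frac,
                    "depth": float(chunk.mean()),
                    "excluded": frac < 0.5,
                }
            )
    return CoverageTrack(sample, pd.DataFrame(rows), bin_size)


# ---------------------------------------------------------------------------
# GC bias


@dataclass
class GCBiasCurve:
    """LOESS fit of mean bin depth against bin GC fraction.

    Evaluation interpolates linearly between fitted points; GC values
    outside the fitted support take the nearest boundary value and are
    recorded in ``n_extrapolated`` at correction time.
    """

    gc: np.ndarray
    depth: np.ndarray
    span: float

    def __call__(self, gc) -> np.ndarray:
        return np.interp(np.asarray(gc, dtype=float), self.gc, self.depth)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.gc[0]), float(self.gc[-1])


def gc_bias_curve(track: CoverageTrack, gc: np.ndarray, span: float = 0.3) -> GCBiasCurve:
    """Fit depth ~ GC by LOESS over non-excluded bins."""
    use = (~track.bins["excluded"]).to_numpy()
    x = np.asarray(gc, dtype=float)[use]
    y = track.bins["depth"].to_numpy(dtype=float)[use]
    fitted = sm.nonparametric.lowess(y, x, frac=span, return_sorted=True)
    gx, gy = fitted[:, 0], fitted[:, 1]
    # collapse duplicate GC values so interpolation is well defined
    gx, uniq = np.unique(gx, return_index=True)
    return GCBiasCurve(gx, gy[uniq], span)


def gc_correct(
    track: CoverageTrack, gc: np.ndarray, span: float = 0.3
) -> tuple[CoverageTrack, GCBiasCurve, int]:
    """Divide out the LOESS-expected depth at each bin's GC.

    corrected = observed * (global median depth) / expected(GC); the global
    median of corrected depths therefore stays at the observed median. Bins
    whose GC lies outside the fitted support use the nearest fitted value
    (their count is returned).
    """
    curve = gc_bias_curve(track, gc, span=span)
    gc = np.asarray(gc, dtype=float)
    use = (~track.bins["excluded"]).to_numpy()
    med = float(np.median(track.bins["depth"].to_numpy()[use]))
    expected = curve(gc)
    expected = np.where(expected <= 0, np.nan, expected)
    out = track.copy()
    corrected = track.bins["depth"].to_numpy() * med / expected
    out.bins["depth"] = corrected
    out.bins.loc[np.isnan(corrected), "excluded"] = True
    lo, hi = curve.support
    n_extrapolated = int(((gc < lo) | (gc > hi)).sum())
    return out, curve, n_extrapolated


# ---------------------------------------------------------------------------
# copy number and allele fraction


def chromosome_cn(
    track: CoverageTrack,
    ploidy: int = 1,
    exclude_chroms: tuple[str, ...] = ("chrM", "chrMito"),
) -> pd.Series:
    """Per-chromosome copy number from median corrected bin depth.

    cn = ploidy * median(chromosome bins) / median(genome bins); medians make
    the baseline robust to the aneuploid chromosome itself and to high-copy
    regions (rDNA-like), and the ratio is invariant to global depth rescaling.
    Mitochondrial bins are excluded from the genome baseline.
    """
    usable = track.usable()
    nuclear = usable[~usable["chrom"].isin(exclude_chroms)]
    baseline = float(nuclear["depth"].median())
    if baseline <= 0:
        raise ValueError("non-positive genome-wide median depth")
    cn = nuclear.groupby("chrom", sort=False)["depth"].median() / baseline * ploidy
    cn.name = "cn_estimate"
    return cn


def chromosome_allele_fraction(allele_counts: pd.DataFrame) -> pd.Series:
    """Mean per-site major-allele read fraction per chromosome.

    ``allele_counts`` columns: chrom, reads_p1, reads_p2. Each informative
    site contributes max(p1, p2) / (p1 + p2); a chromosome that carries one
    haplotype (euploid or mitotic gain) sits near 1, a meiotic disomy near
    0.5. Folding at each site keeps the statistic meaningful on a
    recombinant chromosome, at the cost of a finite-depth bias: at per-site
    depth d the balanced expectation is E[max(X, d-X)]/d (~0.55 at d=60),
    not exactly 0.5. Zero-depth sites are ignored.
    """
    counts = allele_counts[["chrom", "reads_p1", "reads_p2"]].copy()
    tot = counts["reads_p1"] + counts["reads_p2"]
    counts = counts[tot > 0]
    major = counts[["reads_p1", "reads_p2"]].max(axis=1) / (
        counts["reads_p1"] + counts["reads_p2"]
    )
    af = major.groupby(counts["chrom"], sort=False).mean()
    af.name = "allele_fraction"
    return af


# ---------------------------------------------------------------------------
# classification


@dataclass
class ClassifyParams:
    """Decision thresholds for aneuploidy classes (haploid baseline).

    cn_gain_min separates Poisson depth noise from genuine sub-clonal gains
    (cell fraction >= ~0.15 at 30x); delta brackets CN 2; alpha brackets the
    50% allele fraction of a meiotic disomy; hom_min is the homozygosity
    floor for a single-haplotype (mitotic) gain; min_run_bins is the minimum
    contiguous run of gained bins (10 x 10 kb = 100 kb) to call a partial
    duplication.
    """

    delta: float = 0.2
    alpha: float = 0.1
    cn_gain_min: float = 1.15
    hom_min: float = 0.9
    min_run_bins: int = 10


EUPLOID = "euploid"
MEIOTIC = "meiotic_disomy"
MITOTIC = "mitotic_gain"
PARTIAL = "partial_duplication"
UNRESOLVED = "unresolved"


def _longest_gain_run(depth_ratio: np.ndarray, threshold: float) -> tuple[int, int, int]:
    """(run length, start index, end index) of the longest run above threshold."""
    above = depth_ratio > threshold
    best = (0, 0, 0)
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j < len(above) and above[j]:
                j += 1
            if j - i > best[0]:
                best = (j - i, i, j)
            i = j
        else:
            i += 1
    return best


def classify_aneuploidy(
    sample: str,
    chrom: str,
    cn: float,
    allele_fraction: float,
    segment_profile: pd.DataFrame | None = None,
    params: ClassifyParams | None = None,
) -> AneuploidyCall:
    """Assign one (segregant, chromosome) to an aneuploidy class.

    Decision rules on the CN estimate and folded allele fraction:

    * CN within delta of 2 and allele fraction within alpha of 0.5 -> meiotic
      disomy (MI missegregation, both homologs present in every cell).
    * CN in [cn_gain_min, 2 - delta) with allele fraction >= hom_min ->
      mitotic gain (sub-clonal duplication of the spore's own haplotype).
    * CN below cn_gain_min -> euploid, unless ``segment_profile`` (per-bin
      depth ratios: columns start, end, ratio) shows a contiguous run of at
      least min_run_bins gained bins, which is a partial duplication.
    * Anything else (e.g. CN >= 2 + delta with homozygous calls) ->
      unresolved, reported rather than forced into a class.
    """
    p = params or ClassifyParams()
    segment = None
    if segment_profile is not None and len(segment_profile):
        ratio = segment_profile["ratio"].to_numpy(dtype=float)
        run, i, j = _longest_gain_run(ratio, p.cn_gain_min)
        if run >= p.min_run_bins:
            segment = (
                int(segment_profile["start"].iloc[i]),
                int(segment_profile["end"].iloc[j - 1]),
            )
    whole_gain = cn >= p.cn_gain_min
    if not whole_gain:
        label = PARTIAL if segment is not None else EUPLOID
        return AneuploidyCall(sample, chrom, cn, allele_fraction, label, segment)
    meiotic_cn = 2.0 - p.delta <= cn <= 2.0 + p.delta
    balanced = abs(allele_fraction - 0.5) <= p.alpha
    homozygous = allele_fraction >= p.hom_min
    if meiotic_cn and balanced:
        label = MEIOTIC
    elif p.cn_gain_min <= cn < 2.0 + p.delta and homozygous:
        # homozygous gains up to CN~2 are (near-)clonal post-meiotic
        # duplications; balanced and homozygous bands cannot overlap
        label = MITOTIC
    else:
        label = UNRESOLVED
    return AneuploidyCall(sample, chrom, cn, allele_fraction, label, None)


def call_sample(
    sample: str,
    corrected: CoverageTrack,
    allele_counts: pd.DataFrame | None = None,
    params: ClassifyParams | None = None,
    exclude_chroms: tuple[str, ...] = ("chrM", "chrMito"),
) -> list[AneuploidyCall]:
    """Classify every chromosome of one segregant from its corrected track
    (plus allele counts where available; chromosomes without counts use
    allele fraction 1.0, the euploid expectation)."""
    cn = chromosome_cn(corrected, exclude_chroms=exclude_chroms)
    af = (
        chromosome_allele_fraction(allele_counts)
        if allele_counts is not None
        else pd.Series(dtype=float)
    )
    usable = corrected.usable()
    baseline = float(usable[~usable["chrom"].isin(exclude_chroms)]["depth"].median())
    calls = []
    for chrom, cn_est in cn.items():
        sub = usable[usable["chrom"] == chrom]
        profile = pd.DataFrame(
            {
                "start": sub["start"].to_numpy(),
                "end": sub["end"].to_numpy(),
                "ratio": sub["depth"].to_numpy() / baseline,
            }
        )
        calls.append(
            classify_aneuploidy(
                sample,
                chrom,
                float(cn_est),
                float(af.get(chrom, 1.0)),
                segment_profile=profile,
                params=params,
            )
        )
    return calls


def aneuploidy_summary(calls: list[AneuploidyCall], cohort_size: int) -> dict:
    """Cohort table: counts and percentages by class and by chromosome.

    ``pct_aneuploid`` is 100 x (segregants with any non-euploid, resolved
    call) / cohort size. ``chrom_share`` gives, within each non-euploid
    class, the percentage of events on each chromosome (summing to 100).
    """
    df = pd.DataFrame([c.to_dict() for c in calls])
    if len(df) == 0:
        df = pd.DataFrame(columns=["sample", "chrom", "class"])
    events = df[~df["class"].isin([EUPLOID])] if len(df) else df
    aneuploid_samples = events.loc[events["class"] != UNRESOLVED, "sample"].nunique()
    class_counts = events["class"].value_counts().to_dict()
    chrom_share: dict[str, dict[str, float]] = {}
    for label, sub in events.groupby("class"):
        n = len(sub)
        chrom_share[label] = {
            chrom: 100.0 * k / n for chrom, k in sub["chrom"].value_counts().items()
        }
    return {
        "cohort_size": cohort_size,
        "n_aneuploid": int(aneuploid_samples),
        "pct_aneuploid": 100.0 * aneuploid_samples / cohort_size if cohort_size else 0.0,
        "class_counts": class_counts,
        "chrom_share": chrom_share,
        "calls": df,
    }


def plot_coverage(track: CoverageTrack, path: str, cn: pd.Series | None = None) -> None:
    """Per-sample binned coverage panel (one colour block per chromosome)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    usable = track.usable()
    fig, ax = plt.subplots(figsize=(12, 3))
    offset = 0
    med = usable["depth"].median()
    for i, (chrom, sub) in enumerate(usable.groupby("chrom", sort=False)):
        x = offset + (sub["start"] + sub["end"]) / 2.0
        ax.plot(x, sub["depth"] / med, ".", ms=2, color="C0" if i % 2 == 0 else "C1")
        offset += sub["end"].max()
    ax.axhline(1.0, color="grey", lw=0.8)
    ax.axhline(2.0, color="grey", lw=0.8, ls="--")
    ax.set_ylabel("depth / genome median")
    ax.set_xlabel("genome position (concatenated)")
    ax.set_title(track.sample)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
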