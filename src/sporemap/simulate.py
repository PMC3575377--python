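"""Synthetic biparental haploid cross generator.

Emulates the data a ~30x short-read genotyping experiment produces for
segregants of a two-parent yeast cross: a dense parental-informative marker
grid (~1 SNP / 190 bp over 16 chromosomes, ~12.1 Mb), recombinant haplotypes
with Poisson crossover counts (mean 50 per genome), phred-scaled genotype
likelihoods with miscalls and missingness, GC-biased binned coverage, allele
read counts, and barcoded read prefixes — together with ground-truth records
so recovery can be tested end to end.

All functions are deterministic given a :class:`SimConfig` seed; substreams
are derived per stage and per segregant so adding segregants never perturbs
earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    P1,
    P2,
    YEAST_CHROM_LENGTHS,
    CoverageTrack,
    GenotypeMatrix,
    MarkerSet,
    make_bins,
)

_BASES = np.array(["A", "C", "G", "T"], dtype=object)

# stage tags used to derive independent RNG substreams from the global seed
_STAGES = {
    "markers": 1,
    "segregant": 2,
    "likelihoods": 3,
    "coverage": 4,
    "alleles": 5,
    "demux": 6,
    "gc": 7,
}


def stage_rng(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Independent generator for (seed, stage, index)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGES[stage], index)))


@dataclass
class GCBiasModel:
    """Smooth unimodal depth bias as a function of bin GC fraction.

    relative_depth(g) = max(floor, 1 - curvature * (g - center)^2)

    The default curvature depresses coverage noticeably below GC 0.25 while
    staying near 1 over the 0.35-0.55 range typical of the yeast genome.
    """

    center: float = 0.45
    curvature: float = 2.5
    floor: float = 0.1

    def __call__(self, gc) -> np.ndarray:
        gc = np.asarray(gc, dtype=float)
        return np.maximum(self.floor, 1.0 - self.curvature * (gc - self.center) ** 2)


def flat_gc_bias(gc) -> np.ndarray:
    return np.ones_like(np.asarray(gc, dtype=float))


@dataclass
class AneuploidyTruth:
    """A simulated chromosome gain.

    kind 'meiotic' is an MI nondisjunction: both parental homologs present in
    every cell (cell_fraction 1, both haplotypes). kind 'mitotic' is a
    post-meiotic duplication of the segregant's own (single) haplotype in a
    sub-population of cells. kind 'partial' duplicates only ``segment``.
    """

    sample: str
    chrom: str
    kind: str  # meiotic | mitotic | partial
    cell_fraction: float = 1.0
    segment: tuple[int, int] | None = None
    duplicated_haplotype: str = "both"  # P1 | P2 | both

    def __post_init__(self) -> None:
        if self.kind not in ("meiotic", "mitotic", "partial"):
            raise ValueError(f"unknown aneuploidy kind {self.kind!r}")
        if self.kind == "meiotic":
            if self.cell_fraction != 1.0 or self.duplicated_haplotype != "both":
                raise ValueError("meiotic gains have cell_fraction 1 and both haplotypes")
        if self.kind == "mitotic":
            if not (0.0 < self.cell_fraction < 1.0):
                raise ValueError("mitotic gains need cell_fraction in (0, 1)")
            if self.duplicated_haplotype not in ("P1", "P2"):
                raise ValueError("mitotic gains duplicate a single haplotype")
        if self.kind == "partial" and self.segment is None:
            raise ValueError("partial gains need a segment")


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cross."""

    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(YEAST_CHROM_LENGTHS))
    marker_density: float = 1.0 / 190.0
    xo_per_genome: float = 50.0
    error_prob: float = 0.01
    call_rate: float = 0.886
    depth_mean: float = 30.0
    gc_bias: GCBiasModel = field(default_factory=GCBiasModel)
    aneuploidy_events: list[AneuploidyTruth] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(length <= 0 for length in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if not 0.0 <= self.marker_density <= 1.0:
            raise ValueError("marker_density must lie in [0, 1] (markers per bp)")
        if self.xo_per_genome < 0:
            raise ValueError("xo_per_genome must be >= 0")
        for name in ("error_prob", "call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be >= 0")

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gc_bias"] = asdict(self.gc_bias) if isinstance(self.gc_bias, GCBiasModel) else None
        return d


# ---------------------------------------------------------------------------
# markers and haplotypes


def simulate_markers(config: SimConfig, rng: np.random.Generator | None = None) -> MarkerSet:
    """Draw a parental-informative SNP grid at the configured density.

    Per chromosome the marker count is Binomial(L, density) and positions are
    a uniform sample without replacement, so inter-marker spacing is
    approximately geometric with mean 1/density.
    """
    if config.marker_density > 1.0:
        raise ValueError("marker density above 1 per bp: positions would collide")
    rng = rng or stage_rng(config.seed, "markers")
    chroms, poss = [], []
    for chrom, length in config.chrom_lengths.items():
        n = rng.binomial(length, config.marker_density)
        pos = np.sort(rng.choice(length, size=n, replace=False))
        chroms.append(np.full(n, chrom, dtype=object))
        poss.append(pos.astype(np.int64))
    chrom = np.concatenate(chroms) if chroms else np.array([], dtype=object)
    pos = np.concatenate(poss) if poss else np.array([], dtype=np.int64)
    n = len(pos)
    a1 = rng.integers(0, 4, size=n)
    a2 = (a1 + rng.integers(1, 4, size=n)) % 4
    return MarkerSet(chrom, pos, _BASES[a1], _BASES[a2])


def _sample_positions(
    rng: np.random.Generator,
    k: int,
    length: int,
    intensity: tuple[np.ndarray, np.ndarray] | None,
) -> np.ndarray:
    """k crossover breakpoints: uniform, or from a binned intensity track
    (edges, weights) with uniform placement inside the chosen bin."""
    if k == 0:
        return np.empty(0)
    if intensity is None:
        return np.sort(rng.uniform(0.0, length, size=k))
    edges, weights = intensity
    w = np.asarray(weights, dtype=float)
    p = w / w.sum()
    idx = rng.choice(len(p), size=k, p=p)
    lo, hi = edges[idx], edges[idx + 1]
    return np.sort(rng.uniform(lo, hi))


def simulate_segregant(
    markers: MarkerSet,
    config: SimConfig,
    rng: np.random.Generator,
    hotspot_intensity: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """One recombinant haplotype over the marker grid.

    Crossover counts per chromosome are Poisson with mean proportional to the
    chromosome's share of the genome (no interference, no obligate chiasma);
    positions are uniform unless a hotspot intensity track is supplied. The
    starting parent of each chromosome is a fair coin.

    Returns the haplotype vector (P1/P2 codes per marker) and the true
    breakpoint positions per chromosome.
    """
    if len(markers) == 0:
        raise ValueError("marker set is empty")
    total = config.genome_length
    hap = np.empty(len(markers), dtype=np.int8)
    truth: dict[str, np.ndarray] = {}
    for chrom, idx in markers.iter_chromosomes():
        length = config.chrom_lengths[chrom]
        lam = config.xo_per_genome * length / total
        k = rng.poisson(lam)
        track = hotspot_intensity.get(chrom) if hotspot_intensity else None
        xo = _sample_positions(rng, k, length, track)
        start = int(rng.integers(2))
        # parent at a marker flips once per breakpoint to its left
        flips = np.searchsorted(xo, markers.pos[idx], side="right")
        hap[idx] = (start + flips) % 2
        truth[chrom] = xo
    return hap, truth


def simulate_cross(
    markers: MarkerSet,
    n_segregants: int,
    config: SimConfig,
    hotspot_intensity: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    sample_prefix: str = "seg",
) -> tuple[GenotypeMatrix, list[dict[str, np.ndarray]]]:
    """True haplotypes for a cohort; one RNG substream per segregant."""
    haps = np.empty((n_segregants, len(markers)), dtype=np.int8)
    truths = []
    for i in range(n_segregants):
        rng = stage_rng(config.seed, "segregant", i)
        haps[i], t = simulate_segregant(markers, config, rng, hotspot_intensity)
        truths.append(t)
    samples = [f"{sample_prefix}{i:04d}" for i in range(n_segregants)]
    return GenotypeMatrix(samples, markers, haps), truths


# ---------------------------------------------------------------------------
# likelihoods

#: phred range for the disfavoured genotype at a confidently called site
_PL_ALT_LO, _PL_ALT_HI = 30, 90


def simulate_likelihoods(
    truth: GenotypeMatrix, config: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Phred-scaled likelihood pairs (PL_P1, PL_P2) for every call.

    At a called site (probability ``call_rate``) the favoured genotype gets
    PL 0 and the other a positive PL drawn uniformly from [30, 90]; with
    probability ``error_prob`` the two labels are swapped (a miscall). At an
    uncalled site both PLs are 0 (uninformative, decoded as MISSING).
    """
    n, m = truth.calls.shape
    pl1 = np.zeros((n, m), dtype=np.int16)
    pl2 = np.zeros((n, m), dtype=np.int16)
    for i in range(n):
        rng = stage_rng(config.seed, "likelihoods", i)
        called = rng.random(m) < config.call_rate
        flip = rng.random(m) < config.error_prob
        alt = rng.integers(_PL_ALT_LO, _PL_ALT_HI + 1, size=m).astype(np.int16)
        observed = np.where(flip, 1 - truth.calls[i], truth.calls[i])
        is_p1 = observed == P1
        pl1[i] = np.where(called, np.where(is_p1, 0, alt), 0)
        pl2[i] = np.where(called, np.where(is_p1, alt, 0), 0)
    return pl1, pl2


# ---------------------------------------------------------------------------
# coverage and allele counts


def simulate_gc_track(bins: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Smooth per-bin GC fractions (AR(1) wander around 0.38, sd ~0.06)."""
    rng = stage_rng(config.seed, "gc")
    out = bins.copy()
    gcs = np.empty(len(bins))
    pos = 0
    for _, sub in bins.groupby("chrom", sort=False):
        k = len(sub)
        eps = rng.normal(0.0, 1.0, size=k)
        x = np.empty(k)
        x[0] = eps[0]
        for j in range(1, k):  # AR(1), rho 0.9
            x[j] = 0.9 * x[j - 1] + np.sqrt(1 - 0.81) * eps[j]
        gcs[pos : pos + k] = np.clip(0.38 + 0.06 * x, 0.05, 0.85)
        pos += k
    out["gc"] = gcs
    return out


def cn_profile(
    bins: pd.DataFrame, events: list[AneuploidyTruth], sample: str
) -> np.ndarray:
    """Local copy number per bin for one segregant: 1 plus cell_fraction
    inside any gained segment (whole chromosome when segment is None)."""
    cn = np.ones(len(bins))
    for ev in events:
        if ev.sample != sample:
            continue
        on_chrom = (bins["chrom"] == ev.chrom).to_numpy()
        if ev.segment is None:
            cn[on_chrom] += ev.cell_fraction
        else:
            s, e = ev.segment
            inside = on_chrom & (bins["end"].to_numpy() > s) & (bins["start"].to_numpy() < e)
            cn[inside] += ev.cell_fraction
    return cn


def simulate_coverage(
    bins_gc: pd.DataFrame,
    config: SimConfig,
    sample: str,
    sample_index: int = 0,
    events: list[AneuploidyTruth] | None = None,
) -> CoverageTrack:
    """Binned mean depth: Poisson(depth_mean * CN * gc_bias(GC)) per bin."""
    events = config.aneuploidy_events if events is None else events
    rng = stage_rng(config.seed, "coverage", sample_index)
    cn = cn_profile(bins_gc, events, sample)
    lam = config.depth_mean * cn * config.gc_bias(bins_gc["gc"].to_numpy())
    depth = rng.poisson(lam).astype(float)
    df = bins_gc[["chrom", "start", "end"]].copy()
    df["frac_covered"] = np.where(depth > 0, 1.0, 0.0)
    df["depth"] = depth
    df["excluded"] = df["frac_covered"] < 0.5
    bin_size = int((df["end"] - df["start"]).max())
    return CoverageTrack(sample, df, bin_size)


def simulate_per_base_depth(
    length: int, config: SimConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Per-base Poisson(depth_mean) depths for one region (QC fixtures)."""
    rng = rng or stage_rng(config.seed, "coverage")
    return rng.poisson(config.depth_mean, size=length)


def simulate_allele_counts(
    markers: MarkerSet,
    haplotype: np.ndarray,
    config: SimConfig,
    sample: str,
    sample_index: int = 0,
    events: list[AneuploidyTruth] | None = None,
    seq_error: float = 0.002,
) -> pd.DataFrame:
    """Per-site (reads_P1, reads_P2) for one segregant.

    Euploid sites put all reads (minus sequencing error ``seq_error``) on the
    carried allele. A meiotic gain makes every site on the chromosome a
    50/50 binomial split at doubled depth; a mitotic gain keeps reads on the
    carried haplotype (the duplicated copy is identical) at depth scaled by
    1 + cell_fraction.
    """
    events = config.aneuploidy_events if events is None else events
    rng = stage_rng(config.seed, "alleles", sample_index)
    n = len(markers)
    out = markers.to_dataframe()[["chrom", "pos"]]
    p2_prob = np.where(haplotype == P2, 1.0 - seq_error, seq_error)
    depth_scale = np.ones(n)
    for ev in events:
        if ev.sample != sample:
            continue
        on = markers.chrom == ev.chrom
        if ev.segment is not None:
            s, e = ev.segment
            on = on & (markers.pos >= s) & (markers.pos < e)
        depth_scale[on] = 1.0 + ev.cell_fraction
        if ev.duplicated_haplotype == "both":
            p2_prob[on] = 0.5
        # single-haplotype duplication leaves the per-site allele unchanged
    depth = rng.poisson(config.depth_mean * depth_scale)
    reads_p2 = rng.binomial(depth, p2_prob)
    out["reads_p1"] = depth - reads_p2
    out["reads_p2"] = reads_p2
    return out


# ---------------------------------------------------------------------------
# hotspot intensity and demux reads


def hotspot_intensity_track(
    length: int,
    centers: np.ndarray,
    grid: int = 25,
    peak_height: float = 20.0,
    peak_width: float = 800.0,
    depletion_range: tuple[float, float] | None = None,
    depletion_factor: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Crossover intensity on a bp grid: baseline 1 plus Gaussian peaks at
    hotspot centers, optionally multiplied by ``depletion_factor`` where the
    distance to the nearest center falls in ``depletion_range`` (models the
    recombination drop seen right next to DSB hotspots)."""
    edges = np.arange(0, length + grid, grid, dtype=float)
    edges[-1] = length
    mid = 0.5 * (edges[:-1] + edges[1:])
    centers = np.sort(np.asarray(centers, dtype=float))
    j = np.searchsorted(centers, mid)
    left = np.where(j > 0, mid - centers[np.maximum(j - 1, 0)], np.inf)
    right = np.where(j < len(centers), centers[np.minimum(j, len(centers) - 1)] - mid, np.inf)
    dist = np.minimum(left, right)
    w = 1.0 + peak_height * np.exp(-0.5 * (dist / peak_width) ** 2)
    if depletion_range is not None:
        lo, hi = depletion_range
        w = np.where((dist >= lo) & (dist < hi), w * depletion_factor, w)
    return edges, w


def simulate_demux_reads(
    barcodes,
    n: int,
    subst_rate: float,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """(prefix, true barcode id) pairs with independent per-base substitutions."""
    seqs = [(b.id, b.sequence) for b in barcodes]
    if not seqs:
        raise ValueError("barcode set is empty")
    rng = rng or stage_rng(seed, "demux")
    which = rng.integers(0, len(seqs), size=n)
    base_to_code = {b: i for i, b in enumerate(_BASES)}
    codes = np.array([[base_to_code[c] for c in seq] for _, seq in seqs], dtype=np.int8)
    read_codes = codes[which]
    mutate = rng.random(read_codes.shape) < subst_rate
    offset = rng.integers(1, 4, size=read_codes.shape)
    read_codes = np.where(mutate, (read_codes + offset) % 4, read_codes)
    letters = _BASES[read_codes]
    return [("".join(row), seqs[k][0]) for row, k in zip(letters, which)]


# ---------------------------------------------------------------------------
# truth serialization


def truth_crossovers_table(truths: list[dict[str, np.ndarray]], samples: list[str]) -> pd.DataFrame:
    rows = []
    for sample, t in zip(samples, truths):
        for chrom, xo in t.items():
            for p in xo:
                rows.append({"sample": sample, "chrom": chrom, "pos": float(p)})
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos"])


def truth_events_table(events: list[AneuploidyTruth]) -> pd.DataFrame:
    rows = []
    for ev in events:
        s, e = ev.segment if ev.segment else (np.nan, np.nan)
        rows.append(
            {
                "sample": ev.sample,
                "chrom": ev.chrom,
                "kind": ev.kind,
                "cell_fraction": ev.cell_fraction,
                "segment_start": s,
                "segment_end": e,
                "duplicated_haplotype": ev.duplicated_haplotype,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample",
            "chrom",
            "kind",
            "cell_fraction",
            "segment_start",
            "segment_end",
            "duplicated_haplotype",
        ],
    )
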