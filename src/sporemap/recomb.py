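"""Genetic-map estimation, crossover counting, and recombination-rate maps.

The map is estimated per chromosome by EM over a two-state parental-origin
HMM: hidden states are the parental haplotypes, emissions are the observed
calls with symmetric miscall probability ``error_prob``, and each
inter-marker interval carries its own recombination fraction r. The E-step
runs forward-backward across all segregants at once; the M-step sets each
interval's r to the mean posterior switch probability. Recombination
fractions convert to map distance through the Haldane function
``d = -50 ln(1 - 2r)`` (no interference; Kosambi available).

Downstream: genotyping-artifact cleaning (masking short double-crossover
runs in tight genetic spans), crossover counting and event localization,
common-SNP bin partitioning with ΔcM/Δbp rates normalized to mean 1, map
comparison at bin or chromosome scale, and distance profiles of crossover
midpoints around DSB-hotspot centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _hmm
from .core import HET, MISSING, P1, P2, GeneticMap, GenotypeMatrix

R_MIN = 1e-6
R_MAX = 0.5 - 1e-6


# ---------------------------------------------------------------------------
# mapping functions


def haldane_cm(r) -> np.ndarray:
    """Map distance in cM from recombination fraction, d = -50 ln(1-2r)."""
    r = np.asarray(r, dtype=float)
    return -50.0 * np.log1p(-2.0 * np.minimum(r, R_MAX))


def haldane_r(d_cm) -> np.ndarray:
    d = np.asarray(d_cm, dtype=float)
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


def kosambi_cm(r) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * np.minimum(r, R_MAX)))


_MAP_FUNCTIONS = {"haldane": haldane_cm, "kosambi": kosambi_cm}


# ---------------------------------------------------------------------------
# map estimation (Model / Results)


def _direct_count_r(obs: np.ndarray, error_prob: float) -> np.ndarray:
    """Moment initializer: per interval, the mismatch fraction among
    segregants called at both flanking markers, corrected for the symmetric
    miscall rate (p_obs = r(1-2e)^2 + 2e(1-e))."""
    called = np.isin(obs, (P1, P2))
    both = called[:, :-1] & called[:, 1:]
    diff = both & (obs[:, :-1] != obs[:, 1:])
    n = both.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n > 0, diff.sum(axis=0) / np.maximum(n, 1), 0.01)
    e = error_prob
    if e > 0:
        r = (p - 2 * e * (1 - e)) / (1 - 2 * e) ** 2
    else:
        r = p
    return np.clip(r, R_MIN, R_MAX)


@dataclass
class GeneticMapResults:
    """Fitted genetic map with per-chromosome EM diagnostics."""

    model: "GeneticMapModel"
    genetic_map: GeneticMap
    loglik: dict[str, list[float]]
    n_iter: dict[str, int]
    converged: dict[str, bool]
    flagged_intervals: dict[str, np.ndarray]

    def total_length_cm(self) -> float:
        return self.genetic_map.total_length_cm()

    def summary(self) -> str:
        lines = [
            "Genetic map (two-state parental-origin HMM, EM)",
            f"  mapping function : {self.model.map_function}",
            f"  error_prob       : {self.model.error_prob}",
            f"  segregants       : {self.model.matrix.n_samples}",
            "",
            f"{'chrom':<10}{'markers':>9}{'length_cM':>12}{'iter':>6}{'converged':>11}",
        ]
        gm = self.genetic_map
        for c in gm.chromosomes:
            lines.append(
                f"{c:<10}{len(gm.chrom_pos[c]):>9}{gm.chrom_length_cm(c):>12.2f}"
                f"{self.n_iter[c]:>6}{str(self.converged[c]):>11}"
            )
        lines.append("")
        lines.append(f"total map length: {self.total_length_cm():.1f} cM")
        return "\n".join(lines)


@dataclass
class GeneticMapModel:
    """EM estimator of per-interval recombination fractions.

    Parameters
    ----------
    matrix : GenotypeMatrix
        Segregant calls; HET and MISSING are uninformative to the chain.
    error_prob : float
        Symmetric genotyping-error probability of the emission model.
    map_function : str
        'haldane' (default, no interference) or 'kosambi'.
    """

    matrix: GenotypeMatrix
    error_prob: float = 0.01
    map_function: str = "haldane"

    def __post_init__(self) -> None:
        if self.map_function not in _MAP_FUNCTIONS:
            raise ValueError(f"unknown mapping function {self.map_function!r}")

    def fit(self, maxit: int = 1000, tol: float = 1e-5) -> GeneticMapResults:
        """Run EM to convergence (relative log-likelihood change < tol)."""
        to_cm = _MAP_FUNCTIONS[self.map_function]
        chrom_pos, chrom_r, chrom_cm = {}, {}, {}
        loglik: dict[str, list[float]] = {}
        n_iter: dict[str, int] = {}
        converged: dict[str, bool] = {}
        flagged: dict[str, np.ndarray] = {}
        for chrom, idx in self.matrix.markers.iter_chromosomes():
            obs = self.matrix.calls[:, idx]
            n_seg, m = obs.shape
            if m < 2 or n_seg < 2:
                raise ValueError(f"{chrom}: need >=2 markers and >=2 segregants")
            r = _direct_count_r(obs, self.error_prob)
            lls: list[float] = []
            ok = False
            it = 0
            for it in range(1, maxit + 1):
                xi_sum, ll = _hmm.expected_switches(obs, r, self.error_prob)
                if lls and ll < lls[-1] - 1e-6 * abs(lls[-1]):
                    raise AssertionError(f"{chrom}: EM log-likelihood decreased")
                if lls and abs(ll - lls[-1]) < tol * max(1.0, abs(lls[-1])):
                    lls.append(ll)
                    ok = True
                    break
                lls.append(ll)
                r = np.clip(xi_sum / n_seg, R_MIN, R_MAX)
            # intervals next to markers with <2 informative calls are not
            # identifiable; take r from the nearest identifiable neighbours
            col_info = np.isin(obs, (P1, P2)).sum(axis=0)
            bad_marker = col_info < 2
            bad_iv = bad_marker[:-1] | bad_marker[1:]
            if bad_iv.any() and not bad_iv.all():
                good = np.flatnonzero(~bad_iv)
                r[bad_iv] = np.interp(np.flatnonzero(bad_iv), good, r[good])
            pos = self.matrix.markers.pos[idx]
            cm = np.concatenate([[0.0], np.cumsum(to_cm(r))])
            chrom_pos[chrom] = pos
            chrom_r[chrom] = r
            chrom_cm[chrom] = cm
            loglik[chrom] = lls
            n_iter[chrom] = it
            converged[chrom] = ok
            flagged[chrom] = np.flatnonzero(bad_iv)
        gm = GeneticMap(chrom_pos, chrom_r, chrom_cm)
        return GeneticMapResults(self, gm, loglik, n_iter, converged, flagged)


def estimate_map(
    matrix: GenotypeMatrix,
    error_prob: float = 0.01,
    maxit: int = 1000,
    tol: float = 1e-5,
    map_function: str = "haldane",
) -> GeneticMapResults:
    """Functional wrapper around :class:`GeneticMapModel`."""
    return GeneticMapModel(matrix, error_prob, map_function).fit(maxit=maxit, tol=tol)


# ---------------------------------------------------------------------------
# cleaning and crossover counting


def clean_genotypes(
    matrix: GenotypeMatrix,
    genetic_map: GeneticMap,
    maxdist: float = 2.5,
    maxmark: int = 2,
) -> GenotypeMatrix:
    """Mask probable genotyping artifacts that mimic double crossovers.

    Any run of at most ``maxmark`` consecutive same-parent calls flanked on
    both sides by the opposite parent is set to MISSING when the genetic span
    between the flanking calls is at most ``maxdist`` cM. Masked entries are
    only ever set to MISSING — no call is flipped — so crossover counts can
    only decrease. Single pass; HET/MISSING entries are transparent.
    """
    out = matrix.copy()
    for chrom, idx in matrix.markers.iter_chromosomes():
        cm = genetic_map.interpolate_cm(chrom, matrix.markers.pos[idx])
        sub = matrix.calls[:, idx]
        for i in range(matrix.n_samples):
            row = sub[i]
            called = np.flatnonzero((row == P1) | (row == P2))
            if len(called) < 3:
                continue
            vals = row[called]
            # run-length encode the called sequence
            change = np.flatnonzero(np.diff(vals) != 0)
            starts = np.concatenate([[0], change + 1])
            ends = np.concatenate([change, [len(vals) - 1]])
            for s, e in zip(starts[1:-1], ends[1:-1]):  # interior runs only
                if e - s + 1 > maxmark:
                    continue
                span = cm[called[e + 1]] - cm[called[s - 1]]
                if span <= maxdist:
                    out.calls[i, idx[called[s : e + 1]]] = MISSING
    return out


def count_crossovers(matrix: GenotypeMatrix) -> pd.Series:
    """Genome-wide crossover count per segregant.

    Per chromosome, the number of adjacent opposite-parent pairs in the
    MISSING/HET-compressed call sequence; switches spanning chromosome ends
    are impossible by construction.
    """
    counts = np.zeros(matrix.n_samples, dtype=int)
    for chrom, idx in matrix.markers.iter_chromosomes():
        sub = matrix.calls[:, idx]
        for i in range(matrix.n_samples):
            vals = sub[i][(sub[i] == P1) | (sub[i] == P2)]
            if len(vals) > 1:
                counts[i] += int(np.count_nonzero(np.diff(vals)))
    return pd.Series(counts, index=matrix.samples, name="crossovers")


@dataclass
class CrossoverEvent:
    sample: str
    chrom: str
    left: int
    right: int

    @property
    def midpoint(self) -> float:
        return (self.left + self.right) / 2.0


def locate_events(matrix: GenotypeMatrix) -> pd.DataFrame:
    """One row per crossover: flanking called markers and their midpoint.

    The interval runs from the last call before the parental switch to the
    first call after it; uncalled markers inside simply widen the interval.
    """
    rows = []
    for chrom, idx in matrix.markers.iter_chromosomes():
        pos = matrix.markers.pos[idx]
        sub = matrix.calls[:, idx]
        for i, sample in enumerate(matrix.samples):
            called = np.flatnonzero((sub[i] == P1) | (sub[i] == P2))
            vals = sub[i][called]
            for j in np.flatnonzero(np.diff(vals) != 0):
                left = int(pos[called[j]])
                right = int(pos[called[j + 1]])
                rows.append(
                    {
                        "sample": sample,
                        "chrom": chrom,
                        "left": left,
                        "right": right,
                        "midpoint": (left + right) / 2.0,
                    }
                )
    return pd.DataFrame(rows, columns=["sample", "chrom", "left", "right", "midpoint"])


# ---------------------------------------------------------------------------
# rate bins


def partition_bins(
    positions: np.ndarray,
    chrom_length: int,
    min_bp: int = 2000,
    max_bp: int = 3000,
) -> pd.DataFrame:
    """Greedy left-to-right partition of one chromosome on shared SNPs.

    Each bin extends until the first shared SNP at span >= ``min_bp`` and is
    closed there; if no SNP arrives before ``max_bp``, the bin closes at the
    ``max_bp`` boundary instead. A terminal remainder shorter than ``min_bp``
    is merged into the previous bin and flagged; a chromosome shorter than
    ``min_bp`` becomes a single flagged bin.
    """
    positions = np.sort(np.asarray(positions, dtype=np.int64))
    if chrom_length < min_bp:
        return pd.DataFrame({"start": [0], "end": [chrom_length], "flagged": [True]})
    starts, ends = [], []
    s = 0
    while s < chrom_length:
        nxt = positions[(positions >= s + min_bp) & (positions <= s + max_bp)]
        if len(nxt):
            e = int(nxt[0])
        else:
            e = min(s + max_bp, chrom_length)
        starts.append(s)
        ends.append(e)
        s = e
    flagged = [False] * len(starts)
    if len(starts) > 1 and ends[-1] - starts[-1] < min_bp:
        # merge short terminal remainder into the previous bin
        ends[-2] = ends[-1]
        starts.pop()
        ends.pop()
        flagged.pop()
        flagged[-1] = True
    elif ends[-1] - starts[-1] < min_bp:
        flagged[-1] = True
    return pd.DataFrame({"start": starts, "end": ends, "flagged": flagged})


def partition_genome_bins(
    shared_snps: pd.DataFrame,
    chrom_lengths: dict[str, int],
    min_bp: int = 2000,
    max_bp: int = 3000,
) -> pd.DataFrame:
    """Apply :func:`partition_bins` per chromosome; shared_snps has columns
    chrom, pos."""
    frames = []
    for chrom, length in chrom_lengths.items():
        pos = shared_snps.loc[shared_snps["chrom"] == chrom, "pos"].to_numpy()
        df = partition_bins(pos, length, min_bp, max_bp)
        df.insert(0, "chrom", chrom)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def bin_rates(genetic_map: GeneticMap, bins: pd.DataFrame) -> pd.DataFrame:
    """Recombination rate ΔcM/Δbp per bin, normalized to dataset mean 1.

    cM at bin edges is interpolated linearly in bp between markers; bins on
    chromosomes absent from the map get NaN and are ignored by the mean.
    """
    out = bins.copy()
    rates = np.full(len(bins), np.nan)
    for chrom in bins["chrom"].unique():
        m = (bins["chrom"] == chrom).to_numpy()
        if chrom not in genetic_map.chrom_pos:
            continue
        start_cm = genetic_map.interpolate_cm(chrom, bins.loc[m, "start"])
        end_cm = genetic_map.interpolate_cm(chrom, bins.loc[m, "end"])
        span = (bins.loc[m, "end"] - bins.loc[m, "start"]).to_numpy(dtype=float)
        rates[m] = (end_cm - start_cm) / span
    out["rate"] = rates
    mean = np.nanmean(rates)
    out["norm_rate"] = rates / mean if mean > 0 else np.nan
    return out


def compare_maps(
    rates_a: pd.DataFrame, rates_b: pd.DataFrame, scale: str = "bin"
) -> tuple[float, float]:
    """Pearson correlation of two rate maps on a shared partition.

    scale='bin' correlates per-bin rates on common non-missing bins;
    scale='chromosome' first aggregates each chromosome to total cM / total
    bp (sum of rate*span over sum of span) and correlates those.
    """
    key = ["chrom", "start", "end"]
    a = rates_a[key + ["rate"]].rename(columns={"rate": "rate_a"})
    b = rates_b[key + ["rate"]].rename(columns={"rate": "rate_b"})
    merged = a.merge(b, on=key, how="inner").dropna(subset=["rate_a", "rate_b"])
    if scale == "chromosome":
        merged["span"] = merged["end"] - merged["start"]
        g = merged.groupby("chrom", sort=False).apply(
            lambda d: pd.Series(
                {
                    "rate_a": (d["rate_a"] * d["span"]).sum() / d["span"].sum(),
                    "rate_b": (d["rate_b"] * d["span"]).sum() / d["span"].sum(),
                }
            ),
            include_groups=False,
        )
        x, y = g["rate_a"].to_numpy(), g["rate_b"].to_numpy()
    elif scale == "bin":
        x, y = merged["rate_a"].to_numpy(), merged["rate_b"].to_numpy()
    else:
        raise ValueError("scale must be 'bin' or 'chromosome'")
    if len(x) < 3:
        raise ValueError("need >=3 paired observations for a correlation")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# hotspot distance profile


def hotspot_distance_profile(
    events: pd.DataFrame,
    hotspot_centers: pd.DataFrame,
    max_dist: float = 2000.0,
    bin_width: float = 100.0,
) -> pd.DataFrame:
    """Histogram of |event midpoint - nearest hotspot center|.

    ``events`` needs columns chrom, midpoint; ``hotspot_centers`` columns
    chrom, pos. Events farther than ``max_dist`` from every center on their
    chromosome are excluded from the counts.
    """
    edges = np.arange(0.0, max_dist + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for chrom, sub in events.groupby("chrom", sort=False):
        centers = np.sort(
            hotspot_centers.loc[hotspot_centers["chrom"] == chrom, "pos"].to_numpy(dtype=float)
        )
        if len(centers) == 0:
            continue
        mid = sub["midpoint"].to_numpy(dtype=float)
        j = np.searchsorted(centers, mid)
        left = np.where(j > 0, mid - centers[np.maximum(j - 1, 0)], np.inf)
        right = np.where(j < len(centers), centers[np.minimum(j, len(centers) - 1)] - mid, np.inf)
        dist = np.minimum(left, right)
        dist = dist[dist < max_dist]
        h, _ = np.histogram(dist, bins=edges)
        counts += h
    return pd.DataFrame(
        {"dist_lo": edges[:-1], "dist_hi": edges[1:], "count": counts}
    )
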