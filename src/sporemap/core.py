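"""Shared containers for the segregant-genotyping pipeline.

Coordinates are 0-based half-open everywhere in memory; VCF emission adds 1.

Genotype calls are stored as ``int8`` codes: ``P1`` (0) and ``P2`` (1) are the
two parental haplotypes of the cross, ``HET`` (2) marks an apparently
heterozygous call in a haploid segregant (a QC signal, e.g. disomy or
cross-mapping), and ``MISSING`` (-1) marks sites without a confident call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

P1: int = 0
P2: int = 1
HET: int = 2
MISSING: int = -1

CALL_LABELS = {P1: "P1", P2: "P2", HET: "HET", MISSING: "NA"}
LABEL_CODES = {v: k for k, v in CALL_LABELS.items()}

#: S. cerevisiae (S288c R63) nuclear chromosome lengths in bp, ~12.07 Mb total.
YEAST_CHROM_LENGTHS: dict[str, int] = {
    "chrI": 230218,
    "chrII": 813184,
    "chrIII": 316620,
    "chrIV": 1531933,
    "chrV": 576874,
    "chrVI": 270161,
    "chrVII": 1090940,
    "chrVIII": 562643,
    "chrIX": 439888,
    "chrX": 745751,
    "chrXI": 666816,
    "chrXII": 1078177,
    "chrXIII": 924431,
    "chrXIV": 784333,
    "chrXV": 1091291,
    "chrXVI": 948066,
}


@dataclass
class MarkerSet:
    """Ordered parental-informative SNP grid.

    Parameters
    ----------
    chrom : array of str
        Chromosome name per marker, grouped and in karyotype order.
    pos : array of int
        0-based position per marker, strictly increasing within a chromosome.
    allele_p1, allele_p2 : arrays of str
        The two (distinct) parental alleles at each marker.
    """

    chrom: np.ndarray
    pos: np.ndarray
    allele_p1: np.ndarray
    allele_p2: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.allele_p1 = np.asarray(self.allele_p1, dtype=object)
        self.allele_p2 = np.asarray(self.allele_p2, dtype=object)
        n = len(self.pos)
        if not (len(self.chrom) == len(self.allele_p1) == len(self.allele_p2) == n):
            raise ValueError("marker field lengths disagree")
        for _, idx in self.iter_chromosomes():
            p = self.pos[idx]
            if np.any(np.diff(p) <= 0):
                raise ValueError("marker positions must be strictly increasing per chromosome")
        if n and np.any(self.allele_p1 == self.allele_p2):
            raise ValueError("parental alleles must differ at every marker")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c)
        return list(seen)

    def chrom_slice(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == chrom)

    def iter_chromosomes(self):
        for c in self.chromosomes:
            yield c, np.flatnonzero(self.chrom == c)

    def subset(self, index: np.ndarray) -> "MarkerSet":
        return MarkerSet(
            self.chrom[index], self.pos[index], self.allele_p1[index], self.allele_p2[index]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "allele_p1": self.allele_p1,
                "allele_p2": self.allele_p2,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MarkerSet":
        return cls(
            df["chrom"].to_numpy(),
            df["pos"].to_numpy(),
            df["allele_p1"].to_numpy(),
            df["allele_p2"].to_numpy(),
        )


@dataclass
class GenotypeMatrix:
    """Segregants x markers call matrix over {P1, P2, HET, MISSING}."""

    samples: list[str]
    markers: MarkerSet
    calls: np.ndarray  # int8, shape (n_samples, n_markers)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.markers)})"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.samples), self.markers.subset(index), self.calls[:, index])

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.samples), self.markers, self.calls.copy())

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{c}:{p}" for c, p in zip(self.markers.chrom, self.markers.pos)]
        lab = np.vectorize(CALL_LABELS.get, otypes=[object])(self.calls)
        return pd.DataFrame(lab, index=pd.Index(self.samples, name="segregant"), columns=cols)


@dataclass
class GeneticMap:
    """Per-chromosome marker map: bp positions, inter-marker r, cumulative cM."""

    chrom_pos: dict[str, np.ndarray]
    chrom_r: dict[str, np.ndarray]  # len = n_markers - 1 per chromosome
    chrom_cm: dict[str, np.ndarray]

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_pos)

    def total_length_cm(self) -> float:
        return float(sum(cm[-1] for cm in self.chrom_cm.values() if len(cm)))

    def chrom_length_cm(self, chrom: str) -> float:
        cm = self.chrom_cm[chrom]
        return float(cm[-1]) if len(cm) else 0.0

    def interpolate_cm(self, chrom: str, bp) -> np.ndarray:
        """cM at arbitrary bp coordinates, linear in bp between markers,
        clamped to the terminal marker values outside the mapped range."""
        pos = self.chrom_pos[chrom]
        cm = self.chrom_cm[chrom]
        return np.interp(np.asarray(bp, dtype=float), pos.astype(float), cm)

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for c in self.chromosomes:
            frames.append(
                pd.DataFrame({"chrom": c, "pos": self.chrom_pos[c], "cM": self.chrom_cm[c]})
            )
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GeneticMap":
        chrom_pos: dict[str, np.ndarray] = {}
        chrom_cm: dict[str, np.ndarray] = {}
        chrom_r: dict[str, np.ndarray] = {}
        for c, sub in df.groupby("chrom", sort=False):
            chrom_pos[c] = sub["pos"].to_numpy(dtype=np.int64)
            cm = sub["cM"].to_numpy(dtype=float)
            chrom_cm[c] = cm
            d = np.diff(cm)
            chrom_r[c] = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
        return cls(chrom_pos, chrom_r, chrom_cm)


@dataclass
class CoverageTrack:
    """Binned depth over a fixed tiling partition of the genome.

    ``bins`` columns: chrom, start, end, frac_covered, depth, excluded.
    ``frac_covered`` is the fraction of bases covered by >=1 read; bins with
    frac_covered < 0.5 are flagged ``excluded`` and ignored downstream.
    """

    sample: str
    bins: pd.DataFrame
    bin_size: int

    REQUIRED = ("chrom", "start", "end", "frac_covered", "depth", "excluded")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.bins.columns]
        if missing:
            raise ValueError(f"coverage track missing columns: {missing}")

    def usable(self) -> pd.DataFrame:
        return self.bins[~self.bins["excluded"]]

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(self.sample, self.bins.copy(), self.bin_size)


@dataclass
class AneuploidyCall:
    """Copy-number / allele-fraction verdict for one (segregant, chromosome)."""

    sample: str
    chrom: str
    cn_estimate: float
    allele_fraction: float
    label: str  # euploid | meiotic_disomy | mitotic_gain | partial_duplication | unresolved
    segment: tuple[int, int] | None = None

    def to_dict(self) -> dict:
        start, end = self.segment if self.segment else (np.nan, np.nan)
        return {
            "sample": self.sample,
            "chrom": self.chrom,
            "cn_estimate": self.cn_estimate,
            "allele_fraction": self.allele_fraction,
            "class": self.label,
            "segment_start": start,
            "segment_end": end,
        }


def make_bins(chrom_lengths: dict[str, int], bin_size: int) -> pd.DataFrame:
    """Tile every chromosome with fixed-size bins (last bin truncated)."""
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)
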