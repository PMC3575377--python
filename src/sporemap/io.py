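"""File formats: VCF with GT/PL, BED tracks, TSV tables, YAML configs.

Conventions: internal coordinates are 0-based half-open; VCF POS is emitted
1-based and converted back on read; BED is native 0-based half-open. All
tables are plain text with headers and deterministic column order, so every
artifact the pipeline writes can be re-read by the functions here.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    LABEL_CODES,
    MISSING,
    P1,
    P2,
    CoverageTrack,
    GenotypeMatrix,
    MarkerSet,
)

log = logging.getLogger("sporemap")


# ---------------------------------------------------------------------------
# VCF


def write_genotype_vcf(
    path: str | Path,
    markers: MarkerSet,
    pl_p1: np.ndarray,
    pl_p2: np.ndarray,
    samples: list[str],
    calls: np.ndarray | None = None,
) -> None:
    """Emit markers and per-sample haploid GT/PL records (uncompressed VCF).

    REF is the parent-1 allele, ALT the parent-2 allele; POS is 1-based.
    GT is written from ``calls`` when given (P1 -> 0, P2 -> 1, else .),
    otherwise from the smaller PL (tie -> .).
    """
    path = Path(path)
    n, m = len(samples), len(markers)
    if pl_p1.shape != (n, m) or pl_p2.shape != (n, m):
        raise ValueError("PL matrices must be (n_samples, n_markers)")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=PL,Number=G,Type=Integer,'
            'Description="Phred-scaled genotype likelihoods">\n'
        )
        for chrom in markers.chromosomes:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j in range(m):
            fields = [
                str(markers.chrom[j]),
                str(int(markers.pos[j]) + 1),
                ".",
                str(markers.allele_p1[j]),
                str(markers.allele_p2[j]),
                ".",
                "PASS",
                ".",
                "GT:PL",
            ]
            for i in range(n):
                a, b = int(pl_p1[i, j]), int(pl_p2[i, j])
                if calls is not None:
                    c = calls[i, j]
                    gt = "0" if c == P1 else "1" if c == P2 else "."
                else:
                    gt = "0" if a < b else "1" if b < a else "."
                fields.append(f"{gt}:{a},{b}")
            fh.write("\t".join(fields) + "\n")


def read_genotype_vcf(path: str | Path) -> tuple[MarkerSet, np.ndarray, np.ndarray, list[str]]:
    """Read markers and haploid PL pairs from a VCF.

    Returns (markers, pl_p1, pl_p2, samples) with 0-based positions. When
    the PL field is absent, PLs are reconstructed from GT (0 for the called
    allele, 60 for the other; 0,0 for no-calls) with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, poss, ref, alt = [], [], [], []
    pl1_rows, pl2_rows = [], []
    warned = False
    for v in vcf:
        chroms.append(v.CHROM)
        poss.append(v.POS - 1)
        ref.append(v.REF)
        alt.append(v.ALT[0] if v.ALT else "N")
        try:
            pl = v.format("PL")
        except KeyError:  # PL absent from the header entirely
            pl = None
        if pl is not None:
            pl = np.asarray(pl)
            pl1_rows.append(pl[:, 0])
            pl2_rows.append(pl[:, -1])
        else:
            if not warned:
                warnings.warn(f"{path}: no PL field; falling back to GT", stacklevel=2)
                warned = True
            gts = np.array([g[0] for g in v.genotypes])
            pl1_rows.append(np.where(gts == 0, 0, 60))
            pl2_rows.append(np.where(gts == 1, 0, np.where(gts == 0, 60, 0)))
    markers = MarkerSet(
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(ref, dtype=object),
        np.array(alt, dtype=object),
    )
    pl_p1 = np.vstack(pl1_rows).T.astype(np.int32)
    pl_p2 = np.vstack(pl2_rows).T.astype(np.int32)
    pl_p1[pl_p1 < 0] = 0  # cyvcf2 encodes missing as negative sentinels
    pl_p2[pl_p2 < 0] = 0
    return markers, pl_p1, pl_p2, samples


# ---------------------------------------------------------------------------
# genotype matrix TSV


def write_genotype_tsv(path: str | Path, matrix: GenotypeMatrix) -> None:
    """Rows = segregants, columns = chrom:pos, values P1/P2/HET/NA."""
    matrix.to_dataframe().to_csv(path, sep="\t")


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    chroms, poss = [], []
    for col in df.columns:
        chrom, pos = col.rsplit(":", 1)
        chroms.append(chrom)
        poss.append(int(pos))
    # alleles are not carried by the matrix TSV; use placeholders
    n = len(df.columns)
    markers = MarkerSet(
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(["A"] * n, dtype=object),
        np.array(["T"] * n, dtype=object),
    )
    calls = np.vectorize(lambda s: LABEL_CODES.get(s, MISSING), otypes=[np.int8])(
        df.to_numpy(dtype=object)
    )
    return GenotypeMatrix(list(df.index), markers, calls)


# ---------------------------------------------------------------------------
# BED / coverage tracks


def write_bed(path: str | Path, df: pd.DataFrame, score_col: str | None = None) -> None:
    """chrom/start/end (+ optional name, score) as headerless BED."""
    cols = df[["chrom", "start", "end"]].copy()
    if score_col is not None:
        cols["name"] = "."
        cols["score"] = df[score_col]
    cols.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED intervals as a sorted DataFrame (warns when input is unsorted)."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"]
    )
    sorted_df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    if not df[["chrom", "start"]].equals(sorted_df[["chrom", "start"]]):
        warnings.warn(f"{path}: intervals were unsorted; sorted on read", stacklevel=2)
    return sorted_df


def check_tiling(df: pd.DataFrame) -> None:
    """Raise when intervals meant to tile a genome overlap."""
    for chrom, sub in df.groupby("chrom", sort=False):
        s = sub.sort_values("start")
        if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
            raise ValueError(f"{chrom}: overlapping bins where a tiling is required")


def write_coverage_tsv(path: str | Path, track: CoverageTrack) -> None:
    out = track.bins.copy()
    out.insert(0, "sample", track.sample)
    out.to_csv(path, sep="\t", index=False)


def read_coverage_tsv(path: str | Path) -> CoverageTrack:
    df = pd.read_csv(path, sep="\t")
    sample = str(df["sample"].iloc[0]) if len(df) else "sample"
    bins = df.drop(columns=["sample"])
    check_tiling(bins)
    bin_size = int((bins["end"] - bins["start"]).max()) if len(bins) else 0
    return CoverageTrack(sample, bins, bin_size)


# ---------------------------------------------------------------------------
# config


def read_config(path: str | Path, known_keys: set[str]) -> dict:
    """YAML key-value config; unknown keys are rejected outright."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(data) - known_keys
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    return data


def write_config(path: str | Path, data: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
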