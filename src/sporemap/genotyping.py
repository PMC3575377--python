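"""From genotype likelihoods to a clean segregant genotype matrix.

The stages mirror how a two-parent haploid cross is genotyped from short
reads: keep only sites that distinguish the parents (hom-ref in parent 1,
hom-variant in parent 2), call each segregant from its phred-scaled
likelihood pair, drop sites whose cohort allele frequency strays from the
0.5 expected under Mendelian segregation, and fill remaining gaps with a
two-state HMM imputer (a stand-in for haplotype-cluster imputers such as
Beagle, adequate for a biparental haploid cross where the hidden state is
simply parental origin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _hmm
from .core import HET, MISSING, P1, P2, GenotypeMatrix, MarkerSet

# parental genotype codes on candidate sites (diploid-style calls)
HOM_REF = 0
HOM_ALT = 2
PARENT_HET = 1
PARENT_MISSING = -1


def select_informative_sites(
    parent1_calls: np.ndarray,
    parent2_calls: np.ndarray,
    sites: MarkerSet,
) -> tuple[MarkerSet, np.ndarray]:
    """Keep exactly the sites hom-ref in parent 1 and hom-variant in parent 2.

    Sites missing or heterozygous in either parent are dropped. Returns the
    retained :class:`MarkerSet` and the boolean keep mask over input sites.
    """
    p1 = np.asarray(parent1_calls)
    p2 = np.asarray(parent2_calls)
    if not (len(p1) == len(p2) == len(sites)):
        raise ValueError("parental call vectors must match the candidate sites")
    keep = (p1 == HOM_REF) & (p2 == HOM_ALT)
    return sites.subset(np.flatnonzero(keep)), keep


def call_genotypes(
    pl_p1: np.ndarray, pl_p2: np.ndarray, min_gap: float = 20.0
) -> np.ndarray:
    """Haploid calls from phred-scaled likelihood pairs.

    The parent with the smaller PL is called when the PL gap reaches
    ``min_gap`` phred; smaller gaps (including ties) give MISSING.
    """
    pl_p1 = np.asarray(pl_p1)
    pl_p2 = np.asarray(pl_p2)
    if np.any(pl_p1 < 0) or np.any(pl_p2 < 0):
        raise ValueError("PL values must be >= 0")
    gap = np.abs(pl_p1.astype(float) - pl_p2.astype(float))
    calls = np.where(pl_p1 <= pl_p2, P1, P2).astype(np.int8)
    calls[gap < min_gap] = MISSING
    return calls


@dataclass
class AlleleFrequencyReport:
    n_input: int
    n_kept: int
    n_af_removed: int
    n_zero_call: int
    af: np.ndarray  # per input site; NaN where no calls


def allele_frequency_filter(
    matrix: GenotypeMatrix, lo: float = 0.3, hi: float = 0.7
) -> tuple[GenotypeMatrix, AlleleFrequencyReport]:
    """Drop sites whose parental allele frequency leaves [lo, hi] (closed).

    AF is the fraction of P2 among P1/P2 calls at the site; in a two-parent
    cross it should sit near 0.5, so outlying sites flag mismapping or
    systematic miscalls. Sites with zero calls are removed and counted
    separately.
    """
    n1 = (matrix.calls == P1).sum(axis=0)
    n2 = (matrix.calls == P2).sum(axis=0)
    tot = n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(tot > 0, n2 / np.maximum(tot, 1), np.nan)
    zero = tot == 0
    keep = ~zero & (af >= lo) & (af <= hi)
    report = AlleleFrequencyReport(
        n_input=matrix.n_markers,
        n_kept=int(keep.sum()),
        n_af_removed=int((~keep & ~zero).sum()),
        n_zero_call=int(zero.sum()),
        af=af,
    )
    return matrix.subset_markers(np.flatnonzero(keep)), report


def completeness(matrix: GenotypeMatrix) -> pd.Series:
    """Per-segregant fraction of markers with a (P1/P2/HET) call."""
    frac = (matrix.calls != MISSING).mean(axis=1)
    return pd.Series(frac, index=matrix.samples, name="completeness")


def het_rate(matrix: GenotypeMatrix) -> pd.Series:
    """Per-segregant HET fraction; elevated values are disomy evidence."""
    return pd.Series((matrix.calls == HET).mean(axis=1), index=matrix.samples, name="het_rate")


#: default switch intensity, Morgans per bp: 50 crossovers over ~12.07 Mb
DEFAULT_SWITCH_SCALE = 50.0 / 12_071_326.0


def impute_missing(
    matrix: GenotypeMatrix,
    error_prob: float = 0.01,
    switch_scale: float = DEFAULT_SWITCH_SCALE,
    genetic_map=None,
) -> GenotypeMatrix:
    """Fill MISSING calls with the posterior-max parental state.

    Per segregant and chromosome a two-state forward-backward is run with
    emission error ``error_prob`` and inter-marker transition probability
    given by the Haldane recombination fraction of the inter-marker genetic
    distance — taken from ``genetic_map`` when supplied, otherwise
    ``switch_scale`` Morgans per bp times the physical gap. Existing calls
    (including HET, which is uninformative to the chain) are left unchanged;
    a chromosome with no calls at all for a segregant stays missing.
    """
    out = matrix.copy()
    for chrom, idx in matrix.markers.iter_chromosomes():
        obs = matrix.calls[:, idx]
        if obs.shape[1] < 2:
            continue
        if genetic_map is not None:
            d_morgan = np.diff(genetic_map.chrom_cm[chrom]) / 100.0
        else:
            d_morgan = np.diff(matrix.markers.pos[idx]) * switch_scale
        r = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
        r = np.clip(r, 1e-9, 0.5 - 1e-9)
        has_call = np.isin(obs, (P1, P2)).any(axis=1)
        if not has_call.any():
            continue
        gamma = _hmm.posterior(obs[has_call], r, error_prob)
        filled = np.argmax(gamma, axis=2).astype(np.int8)
        sub = out.calls[np.ix_(has_call, idx)]
        sub = np.where(sub == MISSING, filled, sub)
        rows = np.flatnonzero(has_call)
        cols = idx
        out.calls[np.ix_(rows, cols)] = sub
    return out


def linkage_filter(
    matrix: GenotypeMatrix, max_disagree: float = 0.1
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Optional filter for sites out of linkage with their neighbours.

    A site is dropped when its genotype column disagrees with BOTH flanking
    columns in more than ``max_disagree`` of the segregants called at all
    three sites — the signature of systematically misplaced calls rather
    than genuine recombination. Terminal sites are always kept.
    """
    keep = np.ones(matrix.n_markers, dtype=bool)
    calls = matrix.calls
    for chrom, idx in matrix.markers.iter_chromosomes():
        if len(idx) < 3:
            continue
        sub = calls[:, idx]
        informative = np.isin(sub, (P1, P2))
        for j in range(1, len(idx) - 1):
            ok = informative[:, j - 1] & informative[:, j] & informative[:, j + 1]
            n = ok.sum()
            if n == 0:
                continue
            dis = (
                (sub[ok, j] != sub[ok, j - 1]) & (sub[ok, j] != sub[ok, j + 1])
            ).sum()
            if dis / n > max_disagree:
                keep[idx[j]] = False
    return matrix.subset_markers(np.flatnonzero(keep)), keep
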