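"""Inline-barcode design and read demultiplexing.

Multiplexed libraries carry a 6 bp barcode as the first bases of each read.
Barcode sets are designed so every pair differs at >= 3 positions; a read is
assigned to the unique barcode with the fewest mismatches against its 6-mer
prefix (ties or too many mismatches leave it unassigned). At pairwise
distance 3 and a 1-mismatch cap, every single-substitution corruption still
resolves to the true barcode.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

BARCODE_LENGTH = 6
_ALPHABET = "ACGT"
UNASSIGNED = None


@dataclass(frozen=True)
class Barcode:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != BARCODE_LENGTH:
            raise ValueError(f"barcode {self.id}: length must be {BARCODE_LENGTH}")
        if any(c not in _ALPHABET for c in self.sequence):
            raise ValueError(f"barcode {self.id}: alphabet is ACGT only")


@dataclass
class BarcodeSet:
    barcodes: list[Barcode]
    min_pairwise_distance: int

    def __post_init__(self) -> None:
        ids = [b.id for b in self.barcodes]
        if len(set(ids)) != len(ids):
            raise ValueError("barcode ids must be unique")
        for a, b in itertools.combinations(self.barcodes, 2):
            if hamming(a.sequence, b.sequence) < self.min_pairwise_distance:
                raise ValueError(
                    f"barcodes {a.id}/{b.id} closer than {self.min_pairwise_distance}"
                )

    def __len__(self) -> int:
        return len(self.barcodes)

    def __iter__(self):
        return iter(self.barcodes)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": [b.id for b in self.barcodes], "sequence": [b.sequence for b in self.barcodes]}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, min_dist: int = 3) -> "BarcodeSet":
        return cls([Barcode(str(r.id), str(r.sequence)) for r in df.itertuples()], min_dist)


@dataclass
class DemuxAssignment:
    read_id: str
    barcode_id: str | None  # None == unassigned
    mismatches: int


def hamming(a: str, b: str) -> int:
    """Number of differing positions between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def _read_distance(prefix: str, barcode: str) -> int:
    # non-ACGT read characters (e.g. N) mismatch every barcode base
    return sum(x != y or x not in _ALPHABET for x, y in zip(prefix, barcode))


def _balance_cost(seqs: list[str], k: int) -> float:
    """Sum of squared deviations of position-1/2 base counts from k/4."""
    target = k / 4.0
    cost = 0.0
    for pos in (0, 1):
        for base in _ALPHABET:
            n = sum(s[pos] == base for s in seqs)
            cost += (n - target) ** 2
    return cost


def select_barcodes(
    candidates: list[Barcode],
    k: int = 48,
    min_dist: int = 3,
    n_restarts: int = 32,
    seed: int = 0,
) -> BarcodeSet:
    """Pick k mutually distant barcodes with balanced first two bases.

    Greedy with randomized restarts: each restart scans candidates in a
    shuffled order, adding a candidate when it keeps all pairwise Hamming
    distances >= ``min_dist``, preferring (greedily) additions that keep the
    position-1/2 base composition close to k/4 per base. The best feasible
    size-k subset across restarts (smallest balance cost) is returned.

    Raises ``ValueError`` reporting the largest achievable subset when no
    restart reaches size k.
    """
    n = len(candidates)
    if k > n:
        raise ValueError(f"need {k} barcodes but only {n} candidates")
    codes = np.array(
        [[_ALPHABET.index(c) for c in b.sequence] for b in candidates], dtype=np.int8
    )
    dist = (codes[:, None, :] != codes[None, :, :]).sum(axis=2)
    rng = np.random.default_rng(seed)
    best_idx: np.ndarray | None = None
    best_cost = np.inf
    max_size = 0
    target = k / 4.0
    for restart in range(n_restarts):
        order = np.arange(n) if restart == 0 else rng.permutation(n)
        compatible = np.ones(n, dtype=bool)
        counts = np.zeros((2, 4), dtype=float)  # position 0/1 base counts
        chosen: list[int] = []
        while len(chosen) < k:
            feasible = order[compatible[order]]
            if len(feasible) == 0:
                break
            # greedy balance: grow the rarest (position, base) cells first
            c0, c1 = codes[feasible, 0], codes[feasible, 1]
            add_cost = (2 * (counts[0, c0] - target) + 1) + (2 * (counts[1, c1] - target) + 1)
            pick = feasible[int(np.argmin(add_cost))]
            chosen.append(int(pick))
            counts[0, codes[pick, 0]] += 1
            counts[1, codes[pick, 1]] += 1
            compatible &= dist[pick] >= min_dist
        max_size = max(max_size, len(chosen))
        if len(chosen) == k:
            cost = _balance_cost([candidates[i].sequence for i in chosen], k)
            if cost < best_cost:
                best_idx, best_cost = np.array(chosen), cost
    if best_idx is None:
        raise ValueError(
            f"no subset of {k} barcodes at pairwise distance >= {min_dist}; "
            f"maximum achievable size was {max_size}"
        )
    return BarcodeSet([candidates[i] for i in best_idx], min_dist)


def assign_read(
    prefix: str, barcode_set: BarcodeSet, max_mm: int = 1, read_id: str = ""
) -> DemuxAssignment:
    """Best-hit assignment of a 6-mer prefix.

    The read goes to the barcode with the fewest mismatches, provided that
    distance is <= ``max_mm`` and strictly smaller than the runner-up;
    otherwise it is left unassigned. Non-ACGT prefix characters mismatch
    every barcode base.
    """
    if len(prefix) != BARCODE_LENGTH:
        raise ValueError(f"prefix length must be {BARCODE_LENGTH}")
    dists = [(_read_distance(prefix, b.sequence), b.id) for b in barcode_set]
    dists.sort(key=lambda t: t[0])
    d0, bc0 = dists[0]
    unique = len(dists) == 1 or dists[1][0] > d0
    if d0 <= max_mm and unique:
        return DemuxAssignment(read_id, bc0, d0)
    return DemuxAssignment(read_id, UNASSIGNED, d0)


def demux_reads(
    prefixes: list[str], barcode_set: BarcodeSet, max_mm: int = 1
) -> list[DemuxAssignment]:
    return [
        assign_read(p, barcode_set, max_mm=max_mm, read_id=str(i))
        for i, p in enumerate(prefixes)
    ]


def demux_stats(
    pairs: list[tuple[DemuxAssignment, DemuxAssignment]],
) -> dict:
    """Per-barcode read-pair counts plus the discordant-pair fraction.

    A pair is discordant when both mates are assigned but to different
    barcodes (the signature of adapter cross-ligation); pairs with an
    unassigned mate count as unassigned, not discordant.
    """
    counts: dict[str, int] = {}
    discordant = 0
    unassigned = 0
    for a, b in pairs:
        if a.barcode_id is None or b.barcode_id is None:
            unassigned += 1
        elif a.barcode_id != b.barcode_id:
            discordant += 1
        else:
            counts[a.barcode_id] = counts.get(a.barcode_id, 0) + 1
    n = len(pairs)
    return {
        "n_pairs": n,
        "per_barcode": counts,
        "n_discordant": discordant,
        "n_unassigned": unassigned,
        "discordant_fraction": discordant / n if n else 0.0,
    }


def random_candidates(n: int, seed: int = 0) -> list[Barcode]:
    """n random hexamer candidates (convenience for design experiments)."""
    rng = np.random.default_rng(seed)
    seqs = ["".join(_ALPHABET[i] for i in rng.integers(0, 4, BARCODE_LENGTH)) for _ in range(n)]
    return [Barcode(f"BC{i:03d}", s) for i, s in enumerate(seqs)]
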