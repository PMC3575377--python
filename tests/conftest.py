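"""Shared fixtures: small synthetic crosses with realistic per-bp rates.

The toy genome keeps the real per-bp crossover intensity (~4.1e-6 Morgans/bp)
and marker density (~1/190 bp) so genetic spans between markers look like the
full genome's; only the genome size and cohort size are scaled down.
"""

import itertools

import numpy as np
import pytest

import sporemap as sp
from sporemap import genotyping, simulate
from sporemap.demux import Barcode

#: real per-bp crossover intensity: 50 Morgans over ~12.07 Mb
MORGAN_PER_BP = 50.0 / 12_071_326.0

TOY_LENGTHS = {"chr1": 700_000, "chr2": 500_000}


def toy_config(seed: int = 11, **kwargs) -> sp.SimConfig:
    genome = sum(TOY_LENGTHS.values())
    defaults = dict(
        chrom_lengths=dict(TOY_LENGTHS),
        xo_per_genome=MORGAN_PER_BP * genome,
        seed=seed,
    )
    defaults.update(kwargs)
    return sp.SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_cross():
    """120 segregants on a 1.2 Mb two-chromosome genome, default noise."""
    cfg = toy_config()
    markers = simulate.simulate_markers(cfg)
    truth, truths = simulate.simulate_cross(markers, 120, cfg)
    pl1, pl2 = simulate.simulate_likelihoods(truth, cfg)
    calls = genotyping.call_genotypes(pl1, pl2)
    observed = sp.GenotypeMatrix(truth.samples, markers, calls)
    return {
        "config": cfg,
        "markers": markers,
        "truth": truth,
        "truths": truths,
        "observed": observed,
        "pl": (pl1, pl2),
    }


@pytest.fixture(scope="session")
def clean_cross():
    """Noise-free cross: every call correct and present (oracle ground)."""
    cfg = toy_config(seed=13, error_prob=0.0, call_rate=1.0)
    markers = simulate.simulate_markers(cfg)
    truth, truths = simulate.simulate_cross(markers, 60, cfg)
    return {"config": cfg, "markers": markers, "truth": truth, "truths": truths}


@pytest.fixture(scope="session")
def distance3_pool():
    """64 hexamers at pairwise Hamming distance >= 3 (Z4 parity code)."""
    bases = "ACGT"
    pool = []
    for a, b, c in itertools.product(range(4), repeat=3):
        word = (a, b, c, (a + b) % 4, (a + c) % 4, (b + c) % 4)
        pool.append("".join(bases[x] for x in word))
    return [Barcode(f"BC{i:02d}", s) for i, s in enumerate(pool)]
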