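"""End-to-end driver: simulate -> genotype -> map -> rates -> aneuploidy.

Each stage reads only artifacts produced by earlier stages (or the
generator), writes plain-text outputs into the run directory together with
the fully resolved configuration, and contributes counters to a run report.
A single global seed drives every stage through per-stage, per-segregant
substreams, so reruns are byte-identical and adding segregants never
changes existing ones.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnv, genotyping, io, recomb, simulate
from .core import MISSING, YEAST_CHROM_LENGTHS, GenotypeMatrix, make_bins

log = logging.getLogger("sporemap")

ALL_STAGES = ("simulate", "genotype", "map", "rates", "aneuploidy")


@dataclass
class PipelineConfig:
    """Resolved parameters of a pipeline run (YAML-serializable)."""

    n_segregants: int = 96
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    # generator
    marker_density: float = 1.0 / 190.0
    xo_per_genome: float = 50.0
    error_prob: float = 0.01
    call_rate: float = 0.886
    depth_mean: float = 30.0
    # genotyping
    min_gap: float = 20.0
    af_lo: float = 0.3
    af_hi: float = 0.7
    # map
    map_maxit: int = 1000
    map_tol: float = 1e-5
    clean_maxdist: float = 2.5
    clean_maxmark: int = 2
    # rates
    bin_min_bp: int = 2000
    bin_max_bp: int = 3000
    # aneuploidy
    cov_bin_size: int = 10_000
    loess_span: float = 0.3
    allele_thin: int = 20
    write_vcf: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        return cls(**io.read_config(path, known))

    def sim_config(self, events=None) -> simulate.SimConfig:
        return simulate.SimConfig(
            marker_density=self.marker_density,
            xo_per_genome=self.xo_per_genome,
            error_prob=self.error_prob,
            call_rate=self.call_rate,
            depth_mean=self.depth_mean,
            aneuploidy_events=events or [],
            seed=self.seed,
        )


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the toggled stages; returns the run report (also written as
    report.json next to the artifacts)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    io.write_config(outdir / "config.yaml", asdict(config))
    report: dict = {"seed": config.seed, "stages": list(config.stages)}
    t0 = time.time()

    sim = config.sim_config()
    matrix = None
    _markers = _truth = _gmap = None

    def _require(obj, stage: str, needs: str):
        if obj is None:
            raise ValueError(f"stage '{stage}' requires stage '{needs}' to run first")

    if "simulate" in config.stages:
        markers = simulate.simulate_markers(sim)
        truth, truths = simulate.simulate_cross(markers, config.n_segregants, sim)
        pl1, pl2 = simulate.simulate_likelihoods(truth, sim)
        markers.to_dataframe().to_csv(outdir / "markers.tsv", sep="\t", index=False)
        simulate.truth_crossovers_table(truths, truth.samples).to_csv(
            outdir / "truth_crossovers.tsv", sep="\t", index=False
        )
        if config.write_vcf:
            io.write_genotype_vcf(outdir / "segregants.vcf", markers, pl1, pl2, truth.samples)
        np.save(outdir / "_pl_p1.npy", pl1)  # stage hand-off, not an artifact
        np.save(outdir / "_pl_p2.npy", pl2)
        report["simulate"] = {
            "n_markers": len(markers),
            "n_segregants": config.n_segregants,
            "true_mean_crossovers": float(
                np.mean([sum(len(x) for x in t.values()) for t in truths])
            ),
        }
        log.info("simulate: %d markers, %d segregants", len(markers), config.n_segregants)
        _markers, _truth = markers, truth

    if "genotype" in config.stages:
        _require(_markers, "genotype", "simulate")
        calls = genotyping.call_genotypes(
            np.load(outdir / "_pl_p1.npy"), np.load(outdir / "_pl_p2.npy"), config.min_gap
        )
        matrix = GenotypeMatrix(_truth.samples, _markers, calls)
        matrix, af_report = genotyping.allele_frequency_filter(matrix, config.af_lo, config.af_hi)
        comp = genotyping.completeness(matrix)
        imputed = genotyping.impute_missing(matrix, error_prob=config.error_prob)
        io.write_genotype_tsv(outdir / "genotypes.tsv", matrix)
        report["genotype"] = {
            "sites_in": af_report.n_input,
            "sites_kept": af_report.n_kept,
            "sites_af_removed": af_report.n_af_removed,
            "sites_zero_call": af_report.n_zero_call,
            "mean_completeness": float(comp.mean()),
            "mean_completeness_imputed": float(genotyping.completeness(imputed).mean()),
        }
        log.info(
            "genotype: kept %d/%d sites, completeness %.3f",
            af_report.n_kept,
            af_report.n_input,
            comp.mean(),
        )

    if "map" in config.stages:
        _require(matrix, "map", "genotype")
        results = recomb.estimate_map(
            matrix, error_prob=config.error_prob, maxit=config.map_maxit, tol=config.map_tol
        )
        gmap = results.genetic_map
        gmap.to_dataframe().to_csv(outdir / "map.tsv", sep="\t", index=False)
        cleaned = recomb.clean_genotypes(
            matrix, gmap, maxdist=config.clean_maxdist, maxmark=config.clean_maxmark
        )
        counts = recomb.count_crossovers(cleaned)
        events = recomb.locate_events(cleaned)
        events.to_csv(outdir / "events.tsv", sep="\t", index=False)
        counts.to_csv(outdir / "crossover_counts.tsv", sep="\t")
        report["map"] = {
            "total_length_cm": results.total_length_cm(),
            "mean_crossovers": float(counts.mean()),
            "n_events": int(len(events)),
        }
        log.info(
            "map: %.0f cM, mean %.1f crossovers/segregant",
            results.total_length_cm(),
            counts.mean(),
        )
        _gmap = gmap

    if "rates" in config.stages:
        _require(_gmap, "rates", "map")
        snps = pd.DataFrame({"chrom": matrix.markers.chrom, "pos": matrix.markers.pos})
        lengths = {
            c: YEAST_CHROM_LENGTHS.get(c, int(snps.loc[snps["chrom"] == c, "pos"].max()) + 1)
            for c in matrix.markers.chromosomes
        }
        bins = recomb.partition_genome_bins(snps, lengths, config.bin_min_bp, config.bin_max_bp)
        rates = recomb.bin_rates(_gmap, bins)
        rates.to_csv(outdir / "rates.tsv", sep="\t", index=False)
        io.write_bed(outdir / "rates.bed", rates, score_col="norm_rate")
        report["rates"] = {
            "n_bins": int(len(bins)),
            "mean_norm_rate": float(np.nanmean(rates["norm_rate"])),
        }
        log.info("rates: %d bins", len(bins))

    if "aneuploidy" in config.stages:
        _require(_truth, "aneuploidy", "simulate")
        bins10k = make_bins({c: YEAST_CHROM_LENGTHS[c] for c in YEAST_CHROM_LENGTHS}, config.cov_bin_size)
        gc_track = simulate.simulate_gc_track(bins10k, sim)
        thin = slice(None, None, config.allele_thin)
        all_calls = []
        for i, sample in enumerate(_truth.samples):
            track = simulate.simulate_coverage(gc_track, sim, sample, i)
            corrected, _, _ = cnv.gc_correct(track, gc_track["gc"].to_numpy(), config.loess_span)
            thin_idx = np.arange(len(_markers))[thin]
            counts_df = simulate.simulate_allele_counts(
                _markers.subset(thin_idx), _truth.calls[i, thin_idx], sim, sample, i
            )
            all_calls.extend(cnv.call_sample(sample, corrected, counts_df))
        summary = cnv.aneuploidy_summary(all_calls, config.n_segregants)
        summary["calls"].to_csv(outdir / "aneuploidy_calls.tsv", sep="\t", index=False)
        report["aneuploidy"] = {
            "n_aneuploid": summary["n_aneuploid"],
            "pct_aneuploid": summary["pct_aneuploid"],
            "class_counts": summary["class_counts"],
        }
        log.info("aneuploidy: %d aneuploid segregants", summary["n_aneuploid"])

    for tmp in outdir.glob("_pl_p*.npy"):
        tmp.unlink()
    report["runtime_s"] = round(time.time() - t0, 2)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
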