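"""Map estimation, cleaning, crossover counting, rate bins, comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sporemap as sp
from sporemap import recomb
from sporemap.core import MISSING, P1, P2, GeneticMap, GenotypeMatrix, MarkerSet

from conftest import toy_config


def _markers(n, chrom="c", spacing=1000):
    return MarkerSet(
        np.full(n, chrom, dtype=object),
        np.arange(n) * spacing,
        np.full(n, "A", dtype=object),
        np.full(n, "T", dtype=object),
    )


def _uniform_map(n_markers, cm_per_interval, chrom="c", spacing=1000):
    cm = np.arange(n_markers, dtype=float) * cm_per_interval
    return GeneticMap(
        {chrom: np.arange(n_markers) * spacing},
        {chrom: np.full(n_markers - 1, recomb.haldane_r(cm_per_interval))},
        {chrom: cm},
    )


class TestMappingFunctions:
    def test_haldane_closed_forms(self):
        assert recomb.haldane_cm(0.25) == pytest.approx(-50 * np.log(0.5), rel=1e-12)
        assert recomb.haldane_cm(0.25) == pytest.approx(34.657, abs=1e-3)
        assert recomb.haldane_cm(0.0) == 0.0
        assert recomb.haldane_cm(1e-9) == pytest.approx(1e-7, rel=1e-3)

    def test_haldane_roundtrip(self):
        r = np.array([1e-5, 0.01, 0.1, 0.3, 0.49])
        assert np.allclose(recomb.haldane_r(recomb.haldane_cm(r)), r, rtol=1e-10)

    def test_kosambi_below_haldane(self):
        # with interference the same r implies a shorter map distance
        r = np.array([0.05, 0.2, 0.4])
        assert np.all(recomb.kosambi_cm(r) < recomb.haldane_cm(r))


class TestEstimateMap:
    def test_two_marker_direct_count_oracle(self):
        # 100 segregants, 10 recombinant, no error: r = 0.10 exactly and
        # d = -50 ln(0.8) = 11.157 cM
        calls = np.zeros((100, 2), dtype=np.int8)
        calls[:, 0] = P1
        calls[:, 1] = P1
        calls[:10, 1] = P2
        m = GenotypeMatrix([f"s{i}" for i in range(100)], _markers(2), calls)
        res = sp.GeneticMapModel(m, error_prob=0.0).fit()
        r = res.genetic_map.chrom_r["c"][0]
        assert r == pytest.approx(0.10, abs=1e-6)
        assert res.genetic_map.chrom_length_cm("c") == pytest.approx(11.157, abs=1e-3)

    def test_no_recombinants_collapses_to_zero(self):
        calls = np.full((50, 3), P1, dtype=np.int8)
        m = GenotypeMatrix([f"s{i}" for i in range(50)], _markers(3), calls)
        res = sp.estimate_map(m, error_prob=0.0)
        assert res.genetic_map.chrom_length_cm("c") < 1e-3

    def test_loglik_monotone_and_converged(self, small_cross):
        m = small_cross["observed"]
        res = sp.estimate_map(m, error_prob=small_cross["config"].error_prob)
        for chrom, lls in res.loglik.items():
            assert np.all(np.diff(lls) >= -1e-6 * np.abs(lls[:-1]))
            assert res.converged[chrom]

    def test_map_length_recovery_on_small_cohort(self, small_cross):
        # truth: xo_per_genome Morgans = 100 * xo cM expected map length
        cfg = small_cross["config"]
        res = sp.estimate_map(small_cross["observed"], error_prob=cfg.error_prob)
        truth_cm = 100.0 * cfg.xo_per_genome
        assert abs(res.total_length_cm() - truth_cm) / truth_cm < 0.10

    def test_summary_mentions_all_chromosomes(self, small_cross):
        res = sp.estimate_map(small_cross["observed"])
        text = res.summary()
        for chrom in small_cross["markers"].chromosomes:
            assert chrom in text

    def test_degenerate_inputs_rejected(self):
        m = GenotypeMatrix(["s"], _markers(3), np.full((1, 3), P1, dtype=np.int8))
        with pytest.raises(ValueError, match=">=2"):
            sp.estimate_map(m)


class TestCleaning:
    def _matrix(self, rows, cm_per_interval=1.0):
        calls = np.array(rows, dtype=np.int8)
        m = GenotypeMatrix(
            [f"s{i}" for i in range(calls.shape[0])], _markers(calls.shape[1]), calls
        )
        gmap = _uniform_map(calls.shape[1], cm_per_interval)
        return m, gmap

    def test_tight_singleton_masked(self):
        m, gmap = self._matrix([[P1, P2, P1]], cm_per_interval=0.5)
        out = recomb.clean_genotypes(m, gmap)
        assert out.calls[0].tolist() == [P1, MISSING, P1]
        assert recomb.count_crossovers(out)["s0"] == 0
        assert recomb.count_crossovers(m)["s0"] == 2

    def test_run_longer_than_maxmark_unchanged(self):
        m, gmap = self._matrix([[P1, P2, P2, P2, P1]], cm_per_interval=0.1)
        out = recomb.clean_genotypes(m, gmap, maxmark=2)
        assert np.array_equal(out.calls, m.calls)

    def test_wide_singleton_unchanged(self):
        m, gmap = self._matrix([[P1, P2, P1]], cm_per_interval=5.0)  # span 10 cM
        out = recomb.clean_genotypes(m, gmap, maxdist=2.5)
        assert np.array_equal(out.calls, m.calls)

    def test_double_run_masked(self):
        m, gmap = self._matrix([[P1, P2, P2, P1]], cm_per_interval=0.5)
        out = recomb.clean_genotypes(m, gmap, maxmark=2)
        assert out.calls[0].tolist() == [P1, MISSING, MISSING, P1]

    def test_cleaning_never_increases_counts(self, small_cross):
        m = small_cross["observed"]
        res = sp.estimate_map(m, error_prob=small_cross["config"].error_prob)
        cleaned = recomb.clean_genotypes(m, res.genetic_map)
        before = recomb.count_crossovers(m)
        after = recomb.count_crossovers(cleaned)
        assert (after <= before).all()
        # masking only: no call flipped to the other parent
        changed = m.calls != cleaned.calls
        assert np.all(cleaned.calls[changed] == MISSING)


class TestCounting:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ([P1, P1, P2, P2], 1),
            ([P1, MISSING, P2], 1),
            ([P1, P2, P1, P2], 3),
            ([MISSING, MISSING, MISSING], 0),
            ([P1, P1, P1], 0),
        ],
    )
    def test_simple_rows(self, row, expected):
        m = GenotypeMatrix(["s"], _markers(len(row)), np.array([row], dtype=np.int8))
        assert recomb.count_crossovers(m)["s"] == expected

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.sampled_from([P1, P2, MISSING]), min_size=2, max_size=20))
    def test_matches_compression_oracle(self, row):
        # independent oracle: drop MISSING, count sign changes by scanning
        compressed = [v for v in row if v != MISSING]
        expected = sum(a != b for a, b in zip(compressed, compressed[1:]))
        m = GenotypeMatrix(["s"], _markers(len(row)), np.array([row], dtype=np.int8))
        assert recomb.count_crossovers(m)["s"] == expected


class TestEvents:
    def test_midpoint_and_widening(self):
        row = [P1, P1, P2]
        m = GenotypeMatrix(["s"], _markers(3, spacing=1000), np.array([row], dtype=np.int8))
        ev = recomb.locate_events(m)
        assert ev.iloc[0]["midpoint"] == pytest.approx((1000 + 2000) / 2)
        row2 = [P1, MISSING, P2]
        m2 = GenotypeMatrix(["s"], _markers(3, spacing=1000), np.array([row2], dtype=np.int8))
        ev2 = recomb.locate_events(m2)
        # uncalled middle marker widens the interval to the outer markers
        assert ev2.iloc[0]["left"] == 0 and ev2.iloc[0]["right"] == 2000

    def test_event_count_equals_crossover_count(self, small_cross):
        m = small_cross["observed"]
        counts = recomb.count_crossovers(m)
        events = recomb.locate_events(m)
        per_sample = events.groupby("sample").size().reindex(counts.index, fill_value=0)
        assert (per_sample == counts).all()


class TestPartition:
    def test_regular_snps_give_exact_min_bins(self):
        snps = np.arange(500, 20_000, 500)
        bins = recomb.partition_bins(snps, 20_000)
        spans = bins["end"] - bins["start"]
        assert (spans == 2000).all()

    def test_no_snps_cut_at_max(self):
        bins = recomb.partition_bins(np.array([]), 10_000)
        # 1 kb terminal remainder is merged into the previous bin, flagged
        assert bins["end"].tolist() == [3000, 6000, 10_000]
        assert bins["flagged"].tolist() == [False, False, True]

    def test_short_chromosome_single_flagged_bin(self):
        bins = recomb.partition_bins(np.array([500]), 1500)
        assert len(bins) == 1 and bool(bins["flagged"].iloc[0])

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_span_invariant_random_snps(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(5000, 60_000))
        snps = np.unique(rng.integers(0, length, size=rng.integers(1, 80)))
        bins = recomb.partition_bins(snps, length)
        spans = (bins["end"] - bins["start"]).to_numpy()
        ok = bins["flagged"].to_numpy()
        assert np.all((spans[~ok] >= 2000) & (spans[~ok] <= 3000))
        # tiling without gaps
        assert bins["start"].iloc[0] == 0 and bins["end"].iloc[-1] == length
        assert np.all(bins["start"].to_numpy()[1:] == bins["end"].to_numpy()[:-1])


class TestRates:
    def test_uniform_map_all_normalized_one(self):
        gmap = _uniform_map(21, 1.0, spacing=1000)  # 20 kb, 1 cM / kb
        bins = recomb.partition_bins(np.arange(0, 20_001, 500), 20_000)
        bins.insert(0, "chrom", "c")
        rates = recomb.bin_rates(gmap, bins)
        assert np.allclose(rates["norm_rate"], 1.0)
        assert np.nanmean(rates["norm_rate"]) == pytest.approx(1.0, abs=1e-12)

    def test_hot_bin_stands_out(self):
        cm = np.concatenate([[0.0], np.cumsum([1.0] * 10 + [5.0] + [1.0] * 9)])
        gmap = GeneticMap(
            {"c": np.arange(21) * 1000},
            {"c": recomb.haldane_r(np.diff(cm))},
            {"c": cm},
        )
        bins = pd.DataFrame(
            {"chrom": "c", "start": np.arange(0, 20_000, 2000), "end": np.arange(2000, 20_001, 2000)}
        )
        rates = recomb.bin_rates(gmap, bins)
        assert rates["norm_rate"].idxmax() == 5  # the 10-12 kb bin holds the hot interval
        assert rates["norm_rate"].max() > 1.5

    def test_hotspot_rate_recovery_from_generator(self):
        # designated hot region with 5x intensity: its bins' mean normalized
        # rate must stand ~5x above background
        from sporemap import simulate, genotyping

        L = 300_000
        hot = (100_000.0, 120_000.0)
        grid = np.arange(0.0, L + 1000, 1000.0)
        w = np.ones(len(grid) - 1)
        w[(grid[:-1] >= hot[0]) & (grid[:-1] < hot[1])] = 5.0
        cfg = sp.SimConfig(
            chrom_lengths={"c": L}, xo_per_genome=3.0, error_prob=0.0, call_rate=1.0, seed=42
        )
        mk = simulate.simulate_markers(cfg)
        truth, _ = simulate.simulate_cross(mk, 400, cfg, hotspot_intensity={"c": (grid, w)})
        res = sp.estimate_map(truth, error_prob=0.0)
        bins = recomb.partition_genome_bins(
            pd.DataFrame({"chrom": "c", "pos": mk.pos}), {"c": L}
        )
        rates = recomb.bin_rates(res.genetic_map, bins)
        in_hot = (rates["start"] >= hot[0]) & (rates["end"] <= hot[1])
        ratio = rates.loc[in_hot, "norm_rate"].mean() / rates.loc[~in_hot, "norm_rate"].mean()
        assert 3.5 < ratio < 6.5


class TestCompare:
    def _rates(self, values, start=0):
        n = len(values)
        return pd.DataFrame(
            {
                "chrom": ["c1"] * (n // 2) + ["c2"] * (n - n // 2),
                "start": np.arange(n) * 2000,
                "end": (np.arange(n) + 1) * 2000,
                "rate": values,
            }
        )

    def test_identical_maps_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        a = self._rates(rng.gamma(2.0, 1.0, 40))
        r, p = recomb.compare_maps(a, a, scale="bin")
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(1)
        a = self._rates(rng.gamma(2.0, 1.0, 1000))
        b = self._rates(rng.gamma(2.0, 1.0, 1000))
        r, _ = recomb.compare_maps(a, b, scale="bin")
        assert abs(r) < 0.1

    def test_attenuation_matches_noise_model(self):
        # two noisy copies of one truth: E[r] = var(truth)/(var(truth)+var(noise))
        rng = np.random.default_rng(2)
        n = 4000
        truth = rng.gamma(4.0, 1.0, n)
        sd = 1.0
        a = self._rates(truth + rng.normal(0, sd, n))
        b = self._rates(truth + rng.normal(0, sd, n))
        r, _ = recomb.compare_maps(a, b, scale="bin")
        expect = truth.var() / (truth.var() + sd**2)
        assert abs(r - expect) < 0.05

    def test_chromosome_scale_aggregates_before_correlating(self):
        df = pd.DataFrame(
            {
                "chrom": ["c1", "c1", "c2", "c2", "c3", "c3"],
                "start": [0, 2000] * 3,
                "end": [2000, 4000] * 3,
                "rate": [1.0, 3.0, 2.0, 2.0, 5.0, 1.0],
            }
        )
        other = df.copy()
        other["rate"] = df["rate"] * 2
        r, _ = recomb.compare_maps(df, other, scale="chromosome")
        assert r == pytest.approx(1.0)

    def test_mismatched_partitions_rejected(self):
        a = self._rates(np.ones(10))
        b = self._rates(np.ones(10))
        b["start"] += 1
        with pytest.raises(ValueError, match=">=3"):
            recomb.compare_maps(a, b)


class TestHotspotProfile:
    def test_events_at_centers_all_in_first_bin(self):
        centers = pd.DataFrame({"chrom": "c", "pos": [10_000.0, 50_000.0]})
        ev = pd.DataFrame({"chrom": "c", "midpoint": [10_000.0, 50_000.0, 10_000.0]})
        prof = recomb.hotspot_distance_profile(ev, centers, max_dist=2000, bin_width=100)
        assert prof["count"].iloc[0] == 3
        assert prof["count"].iloc[1:].sum() == 0

    def test_uniform_events_flat_profile(self):
        rng = np.random.default_rng(3)
        centers = pd.DataFrame({"chrom": "c", "pos": np.arange(50_000, 1_000_000, 50_000, dtype=float)})
        ev = pd.DataFrame({"chrom": "c", "midpoint": rng.uniform(0, 1_000_000, 200_000)})
        prof = recomb.hotspot_distance_profile(ev, centers, max_dist=2000, bin_width=200)
        counts = prof["count"].to_numpy(dtype=float)
        # uniform positions, far-apart centers: each distance ring is equally
        # likely, so bins deviate from their mean by sampling noise only
        assert counts.std() / counts.mean() < 0.05

    def test_total_counts_respect_max_dist(self):
        centers = pd.DataFrame({"chrom": "c", "pos": [10_000.0]})
        ev = pd.DataFrame({"chrom": "c", "midpoint": [10_100.0, 15_000.0]})
        prof = recomb.hotspot_distance_profile(ev, centers, max_dist=2000, bin_width=100)
        assert prof["count"].sum() == 1
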