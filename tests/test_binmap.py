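"""Bin map: window calling, filters, imputation, bins, map functions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import binqtl as b
from binqtl.binmap import QCConfig
from binqtl.codes import AA, AB, BB, MISSING


def _cfg(**kw):
    defaults = dict(min_genotyped=5)
    defaults.update(kw)
    return QCConfig(**defaults)


class TestCallWindows:
    def test_unanimous_window_calls_homozygote(self):
        calls = np.full(15, AA, dtype=np.int8)
        out = b.call_windows(calls, _cfg())
        assert (out == AA).all()

    def test_balanced_window_calls_het(self):
        calls = np.array([AA, BB] * 10, dtype=np.int8)
        out = b.call_windows(calls, _cfg())
        assert (out == AB).all()

    def test_all_missing_stays_missing(self):
        calls = np.full(40, MISSING, dtype=np.int8)
        assert (b.call_windows(calls, _cfg()) == MISSING).all()

    def test_sparse_observations_below_minimum_stay_missing(self):
        calls = np.full(40, MISSING, dtype=np.int8)
        calls[[3, 17, 30]] = AA  # < min_window_informative
        assert (b.call_windows(calls, _cfg()) == MISSING).all()

    def test_smooths_isolated_errors(self):
        calls = np.full(60, AA, dtype=np.int8)
        calls[[10, 35]] = BB
        out = b.call_windows(calls, _cfg())
        assert (out == AA).all()


class TestBreakpoints:
    def test_constant_track_has_none(self):
        pos = np.arange(10) * 1000
        track = np.full(10, AA, dtype=np.int8)
        assert len(b.detect_breakpoints(track, pos)) == 0

    def test_single_transition_at_flanking_midpoint(self):
        pos = np.arange(10) * 1000
        track = np.array([AA] * 5 + [BB] * 5, dtype=np.int8)
        bp = b.detect_breakpoints(track, pos)
        assert len(bp) == 1
        assert bp["mid_pos"].iloc[0] == (pos[4] + pos[5]) // 2

    def test_missing_calls_skipped(self):
        pos = np.arange(6) * 100
        track = np.array([AA, MISSING, AA, MISSING, BB, BB], dtype=np.int8)
        bp = b.detect_breakpoints(track, pos)
        assert len(bp) == 1
        assert bp["left_snp"].iloc[0] == 2 and bp["right_snp"].iloc[0] == 4


class TestLineFilter:
    @pytest.mark.parametrize(
        "het,breaks,n_geno,kept",
        [
            (0.09, 150, 25_000, True),
            (0.11, 150, 25_000, False),
            (0.09, 201, 25_000, False),
            (0.09, 150, 19_000, False),
        ],
    )
    def test_thresholds(self, het, breaks, n_geno, kept):
        stats = pd.DataFrame(
            {"line": ["l1"], "n_genotyped": [n_geno], "heterozygosity": [het],
             "n_breakpoints": [breaks]}
        )
        assert b.filter_lines(stats, QCConfig())[0] == kept

    def test_idempotent(self, rng):
        stats = pd.DataFrame(
            {
                "line": [f"l{i}" for i in range(50)],
                "n_genotyped": rng.integers(15_000, 30_000, 50),
                "heterozygosity": rng.uniform(0, 0.2, 50),
                "n_breakpoints": rng.integers(0, 300, 50),
            }
        )
        keep1 = b.filter_lines(stats, QCConfig())
        keep2 = b.filter_lines(stats[keep1].reset_index(drop=True), QCConfig())
        assert keep2.all()


class TestImputation:
    def test_fully_observed_track_unchanged(self):
        cm = np.arange(20) * 0.5
        track = np.array([AA] * 10 + [BB] * 10, dtype=np.int8)
        assert np.array_equal(b.impute_argmax(track, cm), track)

    def test_single_missing_flanked_by_a(self):
        cm = np.arange(5) * 0.5
        track = np.array([AA, AA, MISSING, AA, AA], dtype=np.int8)
        out = b.impute_argmax(track, cm)
        assert out[2] == AA

    def test_never_alters_observed_calls(self, rng):
        cm = np.sort(rng.uniform(0, 100, 200))
        track = np.where(cm < 50, AA, BB).astype(np.int8)
        noisy = track.copy()
        noisy[rng.random(200) < 0.3] = MISSING
        # plant one contrarian observed call: must survive imputation
        noisy[10] = BB
        out = b.impute_argmax(noisy, cm, error_rate=0.005)
        obs = noisy != MISSING
        assert np.array_equal(out[obs], noisy[obs])

    def test_mask_and_recover_high_accuracy(self, desk_population):
        from binqtl.evaluate import mask_and_recover

        snps = desk_population.snps
        tracks = desk_population.genotypes.copy()
        tracks[tracks == AB] = MISSING
        for chrom in snps.chromosomes:
            idx = snps.chrom_indices(chrom)
            acc = mask_and_recover(
                tracks[:, idx], snps.table["cm"].to_numpy()[idx], 0.05, seed=3
            )
            assert acc >= 0.99

    def test_rejects_empty_and_het(self):
        with pytest.raises(ValueError):
            b.impute_argmax(np.array([], dtype=np.int8), np.array([]))
        with pytest.raises(ValueError):
            b.impute_argmax(np.array([AB], dtype=np.int8), np.array([0.0]))


class TestBins:
    def test_no_breakpoints_one_bin_per_chromosome(self, desk_snps):
        tracks = np.zeros((5, desk_snps.n_snps), dtype=np.int8)
        bm = b.build_bins(tracks, desk_snps, [f"l{i}" for i in range(5)])
        assert bm.n_bins == len(desk_snps.chromosomes)

    def test_one_breakpoint_two_bins(self, desk_snps):
        idx = desk_snps.chrom_indices("chr1")
        tracks = np.zeros((2, desk_snps.n_snps), dtype=np.int8)
        tracks[0, idx[: idx.size // 2]] = BB
        bm = b.build_bins(tracks, desk_snps, ["l0", "l1"])
        assert (bm.bins["chrom"] == "chr1").sum() == 2
        assert (bm.bins["chrom"] == "chr2").sum() == 1

    def test_bins_tile_and_columns_constant(self, desk_population, desk_binmap):
        snps = desk_population.snps
        # tiling: half-open bins cover each chromosome without gap/overlap
        for chrom in snps.chromosomes:
            sub = desk_binmap.bins[desk_binmap.bins["chrom"] == chrom]
            assert sub["start"].iloc[0] == 0
            assert sub["end"].iloc[-1] == snps.chrom_lengths[chrom]
            assert (
                sub["start"].iloc[1:].to_numpy() == sub["end"].iloc[:-1].to_numpy()
            ).all()
        # brute-force oracle: inside every bin each line's genotype is constant
        pos = snps.table["pos"].to_numpy()
        chroms = snps.table["chrom"].to_numpy()
        for k in range(0, desk_binmap.n_bins, 37):
            row = desk_binmap.bins.iloc[k]
            in_bin = (
                (chroms == row["chrom"]) & (pos >= row["start"]) & (pos < row["end"])
            )
            block = desk_population.genotypes[:, in_bin]
            assert (block == block[:, :1]).all()
            assert np.array_equal(block[:, 0], desk_binmap.genotypes[:, k])

    def test_bin_count_monotone_in_population_size(self, desk_snps):
        pop = b.simulate_ril_population(desk_snps, 120, seed=13)
        counts = []
        for n in (30, 60, 120):
            bm = b.build_bins(pop.genotypes[:n], desk_snps, pop.line_ids[:n])
            counts.append(bm.n_bins)
        assert counts[0] <= counts[1] <= counts[2]


class TestBinFilter:
    def _binmap(self, genotypes):
        n_lines, n_bins = genotypes.shape
        bins = pd.DataFrame(
            {
                "bin_id": [f"bin1_{k}" for k in range(n_bins)],
                "chrom": "chr1",
                "start": np.arange(n_bins) * 100,
                "end": (np.arange(n_bins) + 1) * 100,
                "mid_bp": np.arange(n_bins) * 100 + 50,
                "n_snps": 1,
            }
        )
        return b.BinMap(bins, genotypes.astype(np.int8),
                        [f"l{i}" for i in range(n_lines)], {"chr1": n_bins * 100})

    def test_distortion_rule(self):
        col_ok = np.array([AA] * 400 + [BB] * 300 + [AB] * 40)  # ratio 1.33 -> kept
        col_bad = np.array([AA] * 500 + [BB] * 240)  # ratio 2.08 -> removed
        g = np.column_stack([col_ok, col_bad])
        bm = self._binmap(g)
        kept = b.filter_bins(bm, QCConfig())
        assert list(kept.bins["bin_id"]) == ["bin1_0"]

    def test_het_rule(self):
        col = np.array([AA] * 440 + [BB] * 440 + [AB] * 120)  # 12% het
        bm = self._binmap(col[:, None])
        assert b.filter_bins(bm, QCConfig()).n_bins == 0

    def test_idempotent(self, desk_binmap):
        once = b.filter_bins(desk_binmap, QCConfig())
        twice = b.filter_bins(once, QCConfig())
        pd.testing.assert_frame_equal(once.bins, twice.bins)


class TestMapFunctions:
    def test_kosambi_known_values(self):
        assert b.kosambi_distance(0.0) == 0.0
        assert b.kosambi_distance(0.125) == pytest.approx(12.77, abs=0.005)
        # small-r limit: d ~ 100 r cM
        assert b.kosambi_distance(0.001) == pytest.approx(0.1, rel=1e-4)

    def test_rejects_r_half(self):
        with pytest.raises(ValueError):
            b.kosambi_distance(0.5)

    @given(st.floats(0, 0.499))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_kosambi_roundtrip(self, r):
        assert b.kosambi_inverse(b.kosambi_distance(r)) == pytest.approx(r, abs=1e-10)

    @given(st.floats(0, 0.4999))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_selfed_ril_roundtrip(self, big_r):
        r = b.meiotic_from_ril_fraction(big_r)
        assert b.ril_fraction_from_meiotic(r) == pytest.approx(big_r, abs=1e-10)

    def test_closed_form_chain(self):
        # observed R=0.2 -> r=0.125 -> 12.77 cM, against direct evaluation
        r = b.meiotic_from_ril_fraction(0.2)
        assert r == pytest.approx(0.125)
        assert b.kosambi_distance(r) == pytest.approx(
            25 * np.log((1 + 0.25) / (1 - 0.25))
        )


class TestGeneticMap:
    def test_identical_bins_zero_gap(self):
        g = np.tile(np.array([[AA], [BB]] * 10), (1, 3))
        bins = pd.DataFrame(
            {
                "bin_id": ["bin1_1", "bin1_2", "bin1_3"],
                "chrom": "chr1",
                "start": [0, 100, 200],
                "end": [100, 200, 300],
                "mid_bp": [50, 150, 250],
                "n_snps": 1,
            }
        )
        bm = b.BinMap(bins, g.astype(np.int8), [f"l{i}" for i in range(20)], {"chr1": 300})
        mapped = b.estimate_genetic_map(bm)
        assert np.allclose(mapped.bins["cm"], 0.0)

    def test_estimated_length_close_to_truth(self, desk_snps):
        # chromosome of known meiotic length, large population
        pop = b.simulate_ril_population(desk_snps, 670, seed=17)
        bm = b.build_bins(pop.genotypes, desk_snps, pop.line_ids)
        mapped = b.estimate_genetic_map(bm)
        truth_cm = sum(
            desk_snps.table.loc[desk_snps.table["chrom"] == c, "cm"].max()
            - desk_snps.table.loc[desk_snps.table["chrom"] == c, "cm"].min()
            for c in desk_snps.chromosomes
        )
        assert mapped.total_map_length() == pytest.approx(truth_cm, rel=0.10)


class TestBinMapperEndToEnd:
    def test_breakpoint_recall_and_fdr(self):
        from binqtl.evaluate import score_breakpoints

        # dense panel mirroring the study's SNP density regime
        snps = b.simulate_parent_snps(
            60_000, {"chr1": 150_000_000, "chr2": 150_000_000}, seed=31
        )
        pop = b.simulate_ril_population(snps, 100, seed=31)
        raw = b.simulate_gbs_observations(pop, 0.1, 0.01, seed=31)
        expected_obs = 60_000 * (1 - np.exp(-0.1))
        mapper = b.BinMapper(min_genotyped=int(0.5 * expected_obs))
        mapper.fit(raw)
        kept = np.flatnonzero(mapper.kept_lines_)
        window_span_bp = 20 / (1 - np.exp(-0.1)) * 300e6 / 60_000
        score = score_breakpoints(pop, mapper.imputed_, kept, window_span_bp)
        assert score.recall >= 0.90
        assert score.fdr <= 0.05
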