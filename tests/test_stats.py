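"""Trait statistics: variance components, heritability, chi-square,
marker-trait profiles, NIL similarity."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import binqtl as b
from binqtl.codes import AA, AB, BB


def _balanced_table(values, lines, locs=2, years=2, reps=2):
    rows = []
    it = iter(values)
    for i in range(lines):
        for j in range(locs):
            for k in range(years):
                for m in range(reps):
                    rows.append(
                        {"line": f"l{i}", "location": f"loc{j}", "year": f"year{k}",
                         "rep": m + 1, "value": next(it)}
                    )
    return pd.DataFrame(rows)


class TestVarianceComponents:
    def test_constant_values_give_zero_components(self):
        df = _balanced_table(iter([5.0] * 80), lines=10)
        vc = b.fit_variance_components(df)
        assert (vc.var_line, vc.var_line_loc, vc.var_line_year, vc.var_residual) == (
            0.0, 0.0, 0.0, 0.0,
        )

    def test_pure_noise_line_component_near_zero(self, rng):
        df = _balanced_table(iter(rng.normal(size=300 * 8)), lines=300)
        vc = b.fit_variance_components(df)
        assert vc.var_line < 0.05
        assert vc.var_residual == pytest.approx(1.0, rel=0.15)

    def test_recovers_planted_components(self):
        # (line, line:loc, line:year, residual) = (4, 1, 1, 2), 670 lines;
        # averaged over replicates so the 15% check hits estimator bias,
        # not single-draw Monte-Carlo noise
        a, e, r, m = 670, 2, 2, 2
        ests = []
        for s in range(6):
            rng = np.random.default_rng(1000 + s)
            line = rng.normal(0, 2.0, a)
            ll = rng.normal(0, 1.0, (a, e))
            ly = rng.normal(0, 1.0, (a, r))
            res = rng.normal(0, np.sqrt(2.0), (a, e, r, m))
            vals = (
                line[:, None, None, None]
                + ll[:, :, None, None]
                + ly[:, None, :, None]
                + res
            )
            df = _balanced_table(iter(vals.ravel()), lines=a)
            vc = b.fit_variance_components(df)
            ests.append([vc.var_line, vc.var_line_loc, vc.var_line_year, vc.var_residual])
        mean = np.mean(ests, axis=0)
        for got, planted in zip(mean, (4.0, 1.0, 1.0, 2.0)):
            assert got == pytest.approx(planted, rel=0.15)

    def test_single_line_rejected(self):
        df = _balanced_table(iter(range(8)), lines=1)
        with pytest.raises(ValueError):
            b.fit_variance_components(df)


class TestHeritability:
    def test_formula_direct_evaluation(self):
        comps = {"var_line": 4.0, "var_line_loc": 1.0, "var_line_year": 1.0,
                 "var_residual": 2.0}
        assert b.heritability(comps, e=2, r=2) == pytest.approx(4 / 5.5)

    def test_zero_line_variance(self):
        comps = {"var_line": 0.0, "var_line_loc": 1.0, "var_line_year": 0.0,
                 "var_residual": 1.0}
        assert b.heritability(comps, e=2, r=2) == 0.0

    def test_all_zero_rejected(self):
        comps = dict.fromkeys(
            ["var_line", "var_line_loc", "var_line_year", "var_residual"], 0.0
        )
        with pytest.raises(ValueError):
            b.heritability(comps, e=2, r=2)

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, c):
        base = {"var_line": 3.0, "var_line_loc": 0.5, "var_line_year": 0.25,
                "var_residual": 1.5}
        scaled = {k: v * c for k, v in base.items()}
        assert b.heritability(scaled, 2, 2) == pytest.approx(
            b.heritability(base, 2, 2), abs=1e-12
        )

    def test_monotone_in_line_variance(self):
        vals = [
            b.heritability(
                {"var_line": v, "var_line_loc": 1, "var_line_year": 1, "var_residual": 2},
                2, 2,
            )
            for v in (0.5, 1.0, 2.0, 4.0)
        ]
        assert vals == sorted(vals)

    def test_end_to_end_recovery_of_planted_h2(self, desk_snps):
        spec = b.paper_like_phenotype_spec()
        ests = []
        for s in range(12):
            pop = b.simulate_ril_population(desk_snps, 300, seed=600 + s)
            table, truth = b.simulate_phenotypes(pop, spec, seed=600 + s)
            ests.append(b.heritability(b.fit_variance_components(table)))
        assert abs(np.mean(ests) - spec.planted_h2()) < 0.05


class TestChiSquare:
    def test_cob_color_segregation(self):
        # 395 red : 403 white against 1:1
        res = b.chi_square_ratio_test([395, 403], [1, 1])
        assert round(res.p_value, 3) == 0.777

    def test_perfect_ratios(self):
        assert b.chi_square_ratio_test([400, 400], [1, 1]).chi2 == 0.0
        assert b.chi_square_ratio_test([400, 400], [1, 1]).p_value == 1.0
        assert b.chi_square_ratio_test([300, 100], [3, 1]).chi2 == 0.0

    def test_matches_exact_multinomial_on_tiny_counts(self):
        # exact binomial mid-p as the oracle at n = 12: the mid-p correction
        # removes the discreteness (half the point mass at the observed
        # deviation), which is what the continuous chi-square approximates
        for n_a in range(13):
            if n_a == 6:
                continue  # exact 1:1 split: both conventions return p = 1 / mode mass
            n_b = 12 - n_a
            res = b.chi_square_ratio_test([n_a, n_b], [1, 1])
            tail = sum(
                sps.binom.pmf(k, 12, 0.5)
                for k in range(13)
                if abs(k - 6) >= abs(n_a - 6)
            )
            boundary = sum(
                sps.binom.pmf(k, 12, 0.5)
                for k in range(13)
                if abs(k - 6) == abs(n_a - 6)
            )
            mid_p = tail - 0.5 * boundary
            assert res.p_value == pytest.approx(mid_p, abs=0.05)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            b.chi_square_ratio_test([0, 0], [1, 1])


class TestMarkerTraitProfile:
    def test_identical_classes_p_one(self):
        g = np.array([AA] * 3 + [BB] * 3)[:, None]
        y = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        prof = b.marker_trait_profile(g, y)
        assert prof["p"].iloc[0] == pytest.approx(1.0)
        assert prof["neglog10_p"].iloc[0] == pytest.approx(0.0)

    def test_matches_hand_computed_welch(self):
        # classes {1,2,3} vs {4,5,6}: t = -3/sqrt(2/3), p from t(4)
        g = np.array([AA] * 3 + [BB] * 3)[:, None]
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        prof = b.marker_trait_profile(g, y)
        t_hand = (2.0 - 5.0) / np.sqrt(1.0 / 3 + 1.0 / 3)
        p_hand = 2 * sps.t.sf(abs(t_hand), 4)  # equal variances -> Welch df = 4
        assert prof["t"].iloc[0] == pytest.approx(t_hand)
        assert prof["p"].iloc[0] == pytest.approx(p_hand)

    def test_peak_near_planted_qtl(self, desk_snps):
        # PCR-marker verification setting: sparse marker grid around the
        # major QTL, large population -> profile peaks at the marker nearest
        # (within one grid spacing of) the QTL
        spec = b.paper_like_phenotype_spec()
        pop = b.simulate_ril_population(desk_snps, 670, seed=71)
        table, truth = b.simulate_phenotypes(pop, spec, seed=71)
        y = b.line_means(table, "loc1", "year1").to_numpy()
        snps = desk_snps
        idx = snps.chrom_indices("chr2")[::5][:20]  # ~0.7 cM grid
        prof = b.marker_trait_profile(
            pop.genotypes[:, idx], y,
            snps.table.iloc[idx][["chrom", "pos"]].reset_index(drop=True),
        )
        best = prof.iloc[prof["neglog10_p"].idxmax()]
        qtl_pos = snps.table["pos"].iloc[truth.qtl_snp_index[0]]
        spacing = np.diff(snps.table["pos"].to_numpy()[idx]).max()
        assert abs(best["pos"] - qtl_pos) <= spacing

    def test_order_invariance(self, rng):
        g = rng.choice([AA, BB, AB], (40, 6))
        y = rng.normal(size=40)
        perm = rng.permutation(6)
        a = b.marker_trait_profile(g, y)
        c = b.marker_trait_profile(g[:, perm], y)
        got = c.set_index(pd.Index(perm[c["marker_index"]]))["p"].sort_index()
        assert np.allclose(a["p"].to_numpy(), got.to_numpy())

    def test_single_class_marker_skipped_with_warning(self, rng):
        g = np.full((10, 1), AA)
        with pytest.warns(UserWarning):
            prof = b.marker_trait_profile(g, rng.normal(size=10))
        assert prof.empty


class TestNilSimilarity:
    def test_published_marker_counts(self):
        # 256 GBS SNPs (20 discordant) + 17 concordant PCR markers
        assert b.nil_similarity(256 + 17, 20) == 92.7

    def test_boundaries(self):
        assert b.nil_similarity(100, 0) == 100.0
        assert b.nil_similarity(100, 100) == 0.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            b.nil_similarity(0, 0)
        with pytest.raises(ValueError):
            b.nil_similarity(10, 11)
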