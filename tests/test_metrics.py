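"""Accuracy statistics against hand values and naive-loop oracles."""

import numpy as np
import pytest

from tagimpute import (
    MISSING,
    GenotypeMatrix,
    HaplotypePanel,
    MarkerMap,
    PosteriorGenotypeSet,
    dosage_r2,
    hpd_interval,
    ia_freq,
    ia_maf,
    ia_overall,
    loess_curve,
    stratify,
    weighted_mean,
)
from tagimpute.metrics import dosage_r2_by_snp

from _oracles import (
    hpd_naive,
    ia_by_snp_naive,
    ia_freq_naive,
    ia_naive,
    pearson_r2_naive,
    weighted_mean_naive,
)


def _gm(dosage):
    d = np.asarray(dosage, dtype=np.int8)
    return GenotypeMatrix(d, MarkerMap.from_positions(np.arange(1, d.shape[1] + 1) * 100))


class TestIAOverall:
    def test_perfect_imputation(self):
        truth = _gm([[0, 1], [2, 1]])
        res = ia_overall(truth, truth.dosage.astype(float))
        assert res.overall == 1.0

    def test_maximal_error(self):
        truth = _gm([[2]])
        res = ia_overall(truth, np.array([[0.0]]))
        assert res.overall == 0.0

    def test_hand_evaluated_dosage_errors(self):
        # one SNP, four animals: g=[0,2,1,1], ghat=[0.5,1.5,1,1]
        truth = _gm([[0], [2], [1], [1]])
        ghat = np.array([[0.5], [1.5], [1.0], [1.0]])
        res = ia_overall(truth, ghat)
        assert res.overall == pytest.approx(1 - (0.5 + 0.5 + 0 + 0) / 8)

    def test_missing_truth_excluded(self):
        truth = _gm([[0, MISSING], [2, 2]])
        ghat = np.array([[0.0, 0.0], [2.0, 2.0]])
        res = ia_overall(truth, ghat)
        assert res.overall == 1.0
        assert list(res.n_by_snp) == [2, 1]

    def test_no_evaluable_entries_raises(self):
        truth = _gm([[MISSING], [MISSING]])
        with pytest.raises(ValueError, match="no evaluable"):
            ia_overall(truth, np.zeros((2, 1)))

    def test_decomposition_identity(self, rng):
        """Overall IA equals both weighted means of its decompositions, exactly."""
        d = rng.integers(0, 3, size=(12, 9)).astype(np.int8)
        d[rng.random(d.shape) < 0.2] = MISSING
        truth = _gm(d)
        ghat = np.clip(d + rng.normal(0, 0.3, d.shape), 0, 2)
        res = ia_overall(truth, ghat)
        snp_mean = np.nansum(res.by_snp * res.n_by_snp) / res.n_by_snp.sum()
        ani_mean = np.nansum(res.by_animal * res.m_by_animal) / res.m_by_animal.sum()
        assert res.overall == pytest.approx(snp_mean, abs=1e-12)
        assert res.overall == pytest.approx(ani_mean, abs=1e-12)


class TestIAFreq:
    def _posterior(self, triples):
        t = np.asarray(triples, dtype=float)
        return PosteriorGenotypeSet(
            t[None, :, :], MarkerMap.from_positions(np.arange(1, t.shape[0] + 1) * 100)
        )

    def test_fixed_genotype(self):
        # reference all AA, predicted all AA -> 1.0
        ref = HaplotypePanel(
            np.zeros((4, 1), dtype=np.int8), MarkerMap.from_positions([100])
        )
        post = self._posterior([[1.0, 0.0, 0.0]])
        assert ia_freq(ref, post)[0] == pytest.approx(1.0)

    def test_hwe_balanced(self):
        # ref genotype pairs AA, AB, BB, AB -> (0.25, 0.5, 0.25); identical
        # prediction -> 0.375
        ref = HaplotypePanel(
            np.array([[0], [0], [0], [1], [1], [1], [1], [0]], dtype=np.int8),
            MarkerMap.from_positions([100]),
        )
        post = self._posterior([[0.25, 0.5, 0.25]])
        assert ia_freq(ref, post)[0] == pytest.approx(0.375)

    def test_disjoint_frequencies(self):
        # ref (0.5, 0.5, 0), val (0, 0.5, 0.5) -> 0.25
        ref = HaplotypePanel(
            np.array([[0], [0], [0], [1]], dtype=np.int8),
            MarkerMap.from_positions([100]),
        )
        post = self._posterior([[0.0, 0.5, 0.5]])
        assert ia_freq(ref, post)[0] == pytest.approx(0.25)

    def test_matches_naive_dot_product(self, rng):
        m = 7
        ref_panel = HaplotypePanel(
            rng.integers(0, 2, size=(10, m)).astype(np.int8),
            MarkerMap.from_positions(np.arange(1, m + 1) * 50),
        )
        raw = rng.random((4, m, 3))
        post = PosteriorGenotypeSet(raw / raw.sum(axis=2, keepdims=True), ref_panel.markers)
        from tagimpute import genotype_frequencies

        expected = ia_freq_naive(
            genotype_frequencies(ref_panel), post.probs.mean(axis=0)
        )
        np.testing.assert_allclose(ia_freq(ref_panel, post), expected, atol=1e-12)


class TestIAMaf:
    def test_perfect_imputation_gives_one(self):
        assert ia_maf(1.0, 0.7) == pytest.approx(1.0)

    def test_no_gain_over_frequency_gives_zero(self):
        assert ia_maf(0.9, 0.9) == pytest.approx(0.0)

    def test_hand_value(self):
        assert ia_maf(0.95, 0.90) == pytest.approx(0.5)

    def test_undefined_at_unity_baseline(self):
        assert np.isnan(ia_maf(0.99, 1.0))

    def test_negative_when_below_baseline(self):
        assert ia_maf(0.5, 0.8) < 0


class TestDosageR2:
    def test_exact_recovery(self):
        g = np.array([0, 1, 2, 1])
        assert dosage_r2(g, g.astype(float)) == pytest.approx(1.0)

    def test_affine_invariance(self):
        g = np.array([0, 1, 2, 2, 0])
        assert dosage_r2(g, 0.3 + 0.5 * g) == pytest.approx(1.0)

    def test_against_textbook_formula(self):
        g = [0, 1, 2, 2]
        ghat = [0.1, 0.9, 1.8, 1.6]
        assert dosage_r2(np.array(g), np.array(ghat)) == pytest.approx(
            pearson_r2_naive(g, ghat), abs=1e-12
        )

    def test_constant_truth_flagged(self):
        assert np.isnan(dosage_r2(np.array([1, 1, 1]), np.array([0.5, 1.0, 1.5])))

    def test_missing_pairs_excluded(self):
        g = np.array([0, MISSING, 2, 1])
        ghat = np.array([0.0, 9.9, 2.0, 1.0])
        assert dosage_r2(g, ghat) == pytest.approx(1.0)


class TestWeightedMean:
    def test_equal_weights_is_mean(self):
        assert weighted_mean([0.2, 0.4, 0.6], [1, 1, 1]) == pytest.approx(0.4)

    def test_zero_weight_drops_value(self):
        assert weighted_mean([0.9, 0.1], [1, 0]) == pytest.approx(0.9)

    def test_hand_value(self):
        assert weighted_mean([0.9, 0.5], [3, 1]) == pytest.approx(0.8)

    def test_nan_excluded_with_weight(self):
        assert weighted_mean([0.9, np.nan], [1, 100]) == pytest.approx(0.9)

    def test_all_flagged_raises(self):
        with pytest.raises(ValueError):
            weighted_mean([np.nan, np.nan], [1, 1])


class TestHPD:
    def test_degenerate_constant_values(self):
        assert hpd_interval(np.full(10, 0.7), 0.95) == (0.7, 0.7)

    def test_uniform_integers_window(self):
        lo, hi = hpd_interval(np.arange(1, 101, dtype=float), 0.95)
        assert (lo, hi) == (1.0, 95.0)

    def test_contains_required_mass(self, rng):
        v = rng.normal(size=500)
        lo, hi = hpd_interval(v, 0.9)
        assert np.mean((v >= lo) & (v <= hi)) >= 0.9

    def test_matches_naive_scan(self, rng):
        for _ in range(20):
            v = rng.normal(size=rng.integers(5, 50))
            assert hpd_interval(v, 0.8) == pytest.approx(hpd_naive(list(v), 0.8))


class TestStratify:
    def test_uniform_accuracy_everywhere(self):
        mm = MarkerMap.from_positions(np.arange(1, 21) * 1000)
        tab = stratify(mm, {"ia": np.full(20, 0.9)}, np.ones(20), by="scaled_position")
        vals = tab["ia"].dropna()
        assert np.allclose(vals, 0.9)

    def test_end_markers_assigned_to_extremes(self):
        mm = MarkerMap.from_positions([100, 5000, 10000])
        tab = stratify(mm, {"ia": np.array([1.0, 0.5, 0.0])}, np.ones(3), by="scaled_position")
        ext = tab.set_index("stratum").loc["extremes"]
        assert ext["n_snp"] == 2
        assert ext["ia"] == pytest.approx(0.5)

    def test_planted_gradient_recovered(self, rng):
        mm = MarkerMap.from_positions(np.arange(1, 101) * 1000)
        sp = mm.scaled_position()
        ia = 0.99 - 0.2 * np.abs(sp - 0.5)  # worse at the ends
        tab = stratify(mm, {"ia": ia}, np.ones(100), by="scaled_position").set_index("stratum")
        assert tab.loc["extremes", "ia"] < tab.loc["other", "ia"] < tab.loc["center", "ia"]

    def test_maf_bins(self, rng):
        mm = MarkerMap.from_positions(np.arange(1, 11) * 1000)
        maf = np.array([0.02, 0.07, 0.12, 0.22, 0.33, 0.41, 0.44, 0.48, 0.03, 0.26])
        tab = stratify(mm, {"ia": np.ones(10)}, np.ones(10), by="maf", maf=maf)
        assert tab["n_snp"].sum() == 10
        assert tab.iloc[0]["n_snp"] == 2  # [0, 0.05)


class TestLoess:
    def test_constant_reproduced(self, rng):
        x = np.sort(rng.random(50))
        _, fit = loess_curve(x, np.full(50, 1.7), span=0.4)
        np.testing.assert_allclose(fit, 1.7, atol=1e-9)

    def test_linear_reproduced(self, rng):
        x = np.sort(rng.random(60))
        y = 2.0 + 3.0 * x
        grid, fit = loess_curve(x, y, span=0.5, degree=1)
        np.testing.assert_allclose(fit, 2.0 + 3.0 * grid, atol=1e-9)

    def test_smooths_noisy_sinusoid(self, rng):
        x = np.linspace(0, 1, 200)
        true = np.sin(2 * np.pi * x)
        y = true + rng.normal(0, 0.3, 200)
        grid, fit = loess_curve(x, y, span=0.25, grid=x)
        rmse_fit = np.sqrt(np.mean((fit - true) ** 2))
        rmse_raw = np.sqrt(np.mean((y - true) ** 2))
        assert rmse_fit < rmse_raw


class TestOracleBattery:
    def test_metrics_match_naive_loops_on_random_instances(self, rng):
        """ia, ia_freq, ia_maf, r2 and weighted means vs naive loops, 300 draws."""
        for _ in range(300):
            n = int(rng.integers(2, 12))
            m = int(rng.integers(1, 10))
            d = rng.integers(0, 3, size=(n, m)).astype(np.int8)
            d[rng.random((n, m)) < 0.15] = MISSING
            if not np.any(d != MISSING):
                continue
            truth = GenotypeMatrix(d, MarkerMap.from_positions(np.arange(1, m + 1) * 10))
            ghat = np.clip(
                np.where(d == MISSING, 1, d) + rng.normal(0, 0.4, (n, m)), 0, 2
            )
            res = ia_overall(truth, ghat)
            assert res.overall == pytest.approx(ia_naive(d, ghat), abs=1e-12)
            np.testing.assert_allclose(
                res.by_snp, ia_by_snp_naive(d, ghat), atol=1e-12
            )
            r2 = dosage_r2_by_snp(truth, ghat)
            for c in range(m):
                col = d[:, c]
                ok = col != MISSING
                exp = (
                    pearson_r2_naive(list(col[ok]), list(ghat[ok, c]))
                    if ok.sum() >= 2
                    else float("nan")
                )
                if np.isnan(exp):
                    assert np.isnan(r2[c])
                else:
                    assert r2[c] == pytest.approx(exp, abs=1e-10)
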