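"""Size factors, BH adjustment, activity filter and the NB Wald test."""

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from diapausemir import (
    ComparisonDesign,
    CountSimConfig,
    MatureArmCountMatrix,
    NBTwoGroupModel,
    ValidationError,
    activity_filter,
    bh_adjust,
    simulate_counts,
    size_factors,
)
from diapausemir.diffexpr import run_comparison

from conftest import metadata_for_design


def _matrix(arr, prefix="s"):
    arr = np.asarray(arr)
    arm_ids = [(f"l{i//2+1}", "5p" if i % 2 == 0 else "3p") for i in range(arr.shape[0])]
    return MatureArmCountMatrix(
        arm_ids, [f"{prefix}{j+1}" for j in range(arr.shape[1])], arr
    )


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = _matrix(np.tile([[10], [20], [30], [40]], (1, 4)))
        np.testing.assert_allclose(size_factors(m), 1.0)

    def test_doubled_column_detected(self):
        base = np.array([[10, 10, 20], [30, 30, 60], [7, 7, 14], [100, 100, 200]])
        sf = size_factors(_matrix(base))
        np.testing.assert_allclose(sf[2] / sf[0], 2.0, rtol=1e-12)
        np.testing.assert_allclose(sf[0], sf[1], rtol=1e-12)

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(8)
        k = rng.negative_binomial(5, 0.05, size=(40, 6)) + 1
        sf = size_factors(_matrix(k))
        # independent brute force
        logg = [np.mean([np.log(k[i, j]) for j in range(6)]) for i in range(40)]
        raw = []
        for j in range(6):
            ratios = [k[i, j] / np.exp(logg[i]) for i in range(40)]
            raw.append(np.median(ratios))
        raw = np.array(raw)
        expected = raw / np.exp(np.mean(np.log(raw)))
        np.testing.assert_allclose(sf, expected, atol=1e-12)

    def test_no_positive_arm_uses_pseudo_reference(self):
        k = np.array([[5, 0, 6, 7], [0, 8, 9, 10], [3, 4, 0, 5], [2, 3, 4, 0]])
        sf = size_factors(_matrix(k))
        assert np.all(sf > 0)
        np.testing.assert_allclose(np.exp(np.mean(np.log(sf))), 1.0, atol=1e-12)


class TestBH:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.005, 0.01, 0.03, 0.04]), [0.02, 0.02, 0.04, 0.04]
        )

    def test_all_ones_and_singleton(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_matches_reference_implementation_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(rng.integers(1, 200))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestActivityFilter:
    def test_strictly_greater_than_ten(self):
        m = _matrix(np.array([[10, 10], [11, 10], [0, 0]]))
        sf = np.ones(2)
        act = activity_filter(m, sf, m.sample_ids)
        assert list(act) == [False, True, False]  # means 10.0, 10.5, 0

    def test_empty_sample_set_rejected(self):
        m = _matrix([[5, 5]])
        with pytest.raises(ValidationError):
            activity_filter(m, np.ones(2), [])


class TestNBTwoGroup:
    def test_antisymmetry_under_group_swap(self, simulated_design):
        cfg = CountSimConfig(n_loci=40, dispersion=0.1,
                             planted_dem_fraction=0.2, seed=12)
        m, _, design = simulate_counts(cfg, simulated_design)
        res = NBTwoGroupModel(m, design).fit()
        swapped = ComparisonDesign("swap", design.group_b, design.group_a)
        res2 = NBTwoGroupModel(m, swapped).fit()
        np.testing.assert_allclose(res2.log2FC, -res.log2FC, atol=1e-10)
        np.testing.assert_allclose(res2.p_raw, res.p_raw, atol=1e-10)

    def test_consistency_limit_two_fold(self):
        # exact 2x group means at large n -> log2FC -> 1
        rng = np.random.default_rng(5)
        n = 400
        mu_b = 500.0
        a = rng.poisson(2 * mu_b, size=(30, n))
        b = rng.poisson(mu_b, size=(30, n))
        m = _matrix(np.hstack([a, b]))
        design = ComparisonDesign("big", m.sample_ids[:n], m.sample_ids[n:])
        res = NBTwoGroupModel(m, design, sf=np.ones(2 * n)).fit()
        assert np.all(np.abs(res.log2FC - 1.0) < 0.05)

    def test_all_zero_arm_keeps_lfc_finite(self, simulated_design):
        cfg = CountSimConfig(n_loci=5, dispersion=0.1, seed=3)
        m, _, design = simulate_counts(cfg, simulated_design)
        k = m.counts.copy()
        k[0, :] = 0
        m2 = MatureArmCountMatrix(m.arm_ids, m.sample_ids, k)
        res = NBTwoGroupModel(m2, design).fit()
        assert np.isfinite(res.log2FC).all()
        assert res.p_raw[0] == 1.0

    def test_summary_reports_counts(self, simulated_design):
        cfg = CountSimConfig(n_loci=30, dispersion=0.1,
                             planted_dem_fraction=0.2, seed=2)
        m, _, design = simulate_counts(cfg, simulated_design)
        meta = metadata_for_design(design)
        res = run_comparison(m, meta, design)
        text = res.summary()
        assert "DEMs" in text and "arms tested" in text

    def test_significant_implies_active_and_threshold(self, simulated_design):
        cfg = CountSimConfig(n_loci=50, planted_dem_fraction=0.2, seed=21)
        m, _, design = simulate_counts(cfg, simulated_design)
        meta = metadata_for_design(design)
        res = run_comparison(m, meta, design)
        df = res.frame()
        sig = df[df.significant]
        assert (sig.active).all()
        assert (sig.p_adj < 0.05).all()
        assert (df.p_adj.dropna() >= df.p_raw[df.p_adj.notna()] - 1e-12).all()
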