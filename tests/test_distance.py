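"""Length binning, bootstrap coverage, and the distance-matched parity test."""

import numpy as np
import pytest
import scipy.stats

import axoncalib as axc
from axoncalib.distance import bin_by_length, edr_slope, parity_test
from axoncalib.types import pair_class_masks, pair_indices

from conftest import make_parcels, symmetric


def _line_parcels(n_left: int, n_right: int):
    return make_parcels(["left"] * n_left + ["right"] * n_right)


class TestBinByLength:
    def test_constant_values_give_flat_bins_with_zero_width_ci(self):
        parcels = _line_parcels(8, 8)
        rng = np.random.default_rng(0)
        lengths = symmetric(rng.uniform(10, 100, (16, 16)))
        values = symmetric(np.full((16, 16), 7.0))
        b = bin_by_length(values, lengths, parcels, "intra", n_bins=4,
                          n_boot=200, seed=1)
        filled = b.counts > 0
        assert np.allclose(b.means[filled], 7.0)
        assert np.allclose(b.ci_low[filled], 7.0)
        assert np.allclose(b.ci_high[filled], 7.0)

    def test_noise_free_exponential_decays_monotonically(self):
        parcels = _line_parcels(10, 10)
        rng = np.random.default_rng(2)
        lengths = symmetric(rng.uniform(5, 200, (20, 20)))
        values = np.exp(-0.03 * lengths)
        np.fill_diagonal(values, 0.0)
        b = bin_by_length(values, lengths, parcels, "intra", n_bins=6,
                          n_boot=50, seed=1)
        filled = b.means[b.counts > 0]
        assert (np.diff(filled) < 0).all()

    def test_empty_bins_reported_not_dropped(self):
        parcels = _line_parcels(4, 4)
        lengths = np.zeros((8, 8))
        # two length clusters with a gap in the middle
        iu = pair_indices(8)
        vals = np.where(np.arange(len(iu[0])) % 2 == 0, 20.0, 180.0)
        lengths[iu] = vals
        lengths = lengths + lengths.T
        values = symmetric(np.full((8, 8), 1.0))
        b = bin_by_length(values, lengths, parcels, "intra", n_bins=8,
                          n_boot=20, seed=0)
        assert len(b.counts) == 8
        assert (b.counts == 0).any()
        assert np.isnan(b.means[b.counts == 0]).all()

    def test_bootstrap_ci_covers_known_mean_about_95_percent(self):
        # values independent of length with known mean; count coverage of the
        # per-bin CI across replicates and bins
        parcels = _line_parcels(17, 1)
        true_mean = 10.0
        covered = total = 0
        for rep in range(120):
            rng = np.random.default_rng(rep)
            lengths = symmetric(rng.uniform(10, 100, (18, 18)))
            values = symmetric(
                np.clip(rng.normal(true_mean, 2.0, (18, 18)), 0.01, None)
            )
            b = bin_by_length(values, lengths, parcels, "intra", n_bins=3,
                              n_boot=400, seed=rep)
            for k in range(3):
                if b.counts[k] < 20:
                    continue
                total += 1
                covered += b.ci_low[k] <= true_mean <= b.ci_high[k]
        assert total > 200
        assert 0.90 <= covered / total <= 0.98


class TestParityTest:
    def test_identical_groups_give_zero_difference_and_p_one(self):
        # the inter pair set replicates the intra (length, value) multiset, so
        # slopes, intercepts and correlations coincide exactly
        parcels = make_parcels(["left"] * 3 + ["right"] * 3)
        lengths = np.zeros((6, 6))
        values = np.zeros((6, 6))
        points = [(50.0, 5.0), (65.0, 4.0), (80.0, 3.0)]
        intra_pairs = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]
        inter_pairs = [(i, j) for i in range(3) for j in range(3, 6)]
        for k, (i, j) in enumerate(intra_pairs + inter_pairs):
            L, v = points[k % 3]
            lengths[i, j] = lengths[j, i] = L
            values[i, j] = values[j, i] = v
        res = parity_test(values, lengths, parcels, n_boot=50, n_perm=99, seed=0)
        assert res.slope_diff == pytest.approx(0.0, abs=1e-12)
        assert res.intercept_diff == pytest.approx(0.0, abs=1e-12)
        assert res.perm_p == 1.0

    def test_noise_free_regression_recovers_decay_rate(self):
        lam = 0.0423
        cfg = axc.GeneratorConfig(n_parcels_per_hemisphere=12, n_subjects=1,
                                  edr_lambda=lam, lognormal_sigma=0.0,
                                  adjacency_boost=1.0, seed=3)
        parcels, lengths, subjects, _ = axc.generate_default_cohort(cfg)
        res = parity_test(subjects[0].streamlines, lengths, parcels,
                          n_boot=20, n_perm=20, seed=0)
        assert res.slope_intra == pytest.approx(-lam, rel=1e-6)
        assert res.slope_inter == pytest.approx(-lam, rel=1e-6)

    def test_shared_decay_rate_rarely_rejected(self):
        rejections = 0
        n_seeds = 30
        for seed in range(n_seeds):
            cfg = axc.GeneratorConfig(n_parcels_per_hemisphere=20, n_subjects=4,
                                      adjacency_boost=1.0, seed=seed)
            parcels, lengths, subjects, _ = axc.generate_default_cohort(cfg)
            mean = axc.mean_streamline_matrix(subjects)
            res = parity_test(mean, lengths, parcels, n_boot=25, n_perm=79,
                              seed=seed)
            rejections += res.perm_p < 0.05
        assert rejections / n_seeds <= 0.1

    def test_detection_rate_rises_with_slope_difference(self):
        # steepen the interhemispheric decay by an extra factor and watch the
        # bootstrap slope-difference CI exclude zero more often
        def detect_rate(extra_lambda: float) -> float:
            hits = 0
            for seed in range(10):
                cfg = axc.GeneratorConfig(n_parcels_per_hemisphere=16,
                                          n_subjects=6, adjacency_boost=1.0,
                                          seed=seed)
                parcels, lengths, subjects, _ = axc.generate_default_cohort(cfg)
                mean = axc.mean_streamline_matrix(subjects)
                masks_full = np.zeros_like(mean, dtype=bool)
                left = parcels.is_left
                masks_full[np.ix_(left, ~left)] = True
                masks_full |= masks_full.T
                steeper = mean * np.where(
                    masks_full, np.exp(-extra_lambda * lengths), 1.0
                )
                res = parity_test(steeper, lengths, parcels, n_boot=60,
                                  n_perm=10, seed=seed)
                lo, hi = res.slope_diff_ci
                hits += not (lo <= 0.0 <= hi)
            return hits / 10

        assert detect_rate(0.05) > detect_rate(0.0)
        assert detect_rate(0.05) >= 0.8

    def test_disjoint_length_domains_rejected(self):
        parcels = make_parcels(["left", "left", "right", "right"])
        lengths = np.zeros((4, 4))
        values = symmetric(np.full((4, 4), 2.0))
        # intra pairs short, inter pairs long, no overlap
        for (i, j), L in {(0, 1): 10.0, (2, 3): 12.0, (0, 2): 200.0,
                          (0, 3): 210.0, (1, 2): 220.0, (1, 3): 230.0}.items():
            lengths[i, j] = lengths[j, i] = L
        with pytest.raises(ValueError, match="common"):
            parity_test(values, lengths, parcels, n_boot=10, n_perm=10, seed=0)

    def test_permutation_p_uniform_under_null(self):
        ps = []
        for seed in range(200):
            cfg = axc.GeneratorConfig(n_parcels_per_hemisphere=24, n_subjects=4,
                                      adjacency_boost=1.0, seed=seed)
            parcels, lengths, subjects, _ = axc.generate_default_cohort(cfg)
            mean = axc.mean_streamline_matrix(subjects)
            res = parity_test(mean, lengths, parcels, n_boot=5, n_perm=149,
                              seed=seed)
            ps.append(res.perm_p)
        assert scipy.stats.kstest(np.array(ps), "uniform").pvalue > 0.01


class TestEdrSlope:
    def test_noise_free_recovery_to_high_precision(self):
        lam = 0.06173
        cfg = axc.GeneratorConfig(n_parcels_per_hemisphere=10, n_subjects=1,
                                  edr_lambda=lam, lognormal_sigma=0.0,
                                  adjacency_boost=1.0, seed=1)
        parcels, lengths, subjects, _ = axc.generate_default_cohort(cfg)
        slope, _ = edr_slope(subjects[0].streamlines, lengths, parcels,
                             exclude_adjacent=False, n_boot=10, seed=0)
        assert slope == pytest.approx(-lam, rel=1e-6)
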