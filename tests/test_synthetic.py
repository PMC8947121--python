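"""Generator contracts: geometry, mirror symmetry, determinism, and the
statistical structure the pipeline assumes (log-normal weights, shared
exponential decay, adjacency boost, callosal-area anchoring)."""

import numpy as np
import pytest
import scipy.stats

import axoncalib as axc
from axoncalib.types import ConfigError, pair_class_masks, pair_indices


class TestParcelTable:
    def test_default_config_parcel_count_and_area_sum(self):
        parcels = axc.generate_parcel_table(axc.GeneratorConfig())
        assert parcels.n_parcels == 360
        assert np.isclose(parcels.areas.sum(), 1.77e5, rtol=1e-9)
        assert (parcels.areas > 0).all()
        assert set(np.unique(parcels.networks)) <= set(range(1, 11))

    def test_mirror_symmetry_of_areas_and_adjacency(self):
        cfg = axc.GeneratorConfig(n_parcels_per_hemisphere=15, seed=2)
        parcels = axc.generate_parcel_table(cfg)
        n = 15
        assert np.allclose(parcels.areas[:n], parcels.areas[n:])
        adj = parcels.adjacency_matrix()
        assert np.array_equal(adj[:n, :n], adj[n:, n:])
        assert not adj[:n, n:].any()  # adjacency never crosses the midline

    def test_hemisphere_adjacency_connected(self):
        from scipy.sparse.csgraph import connected_components

        cfg = axc.GeneratorConfig(n_parcels_per_hemisphere=25, seed=4)
        parcels = axc.generate_parcel_table(cfg)
        adj = parcels.adjacency_matrix()
        n_comp, _ = connected_components(adj[:25, :25], directed=False)
        assert n_comp == 1

    def test_two_parcels_per_hemisphere_single_edge(self):
        cfg = axc.GeneratorConfig(n_parcels_per_hemisphere=2, seed=0)
        parcels = axc.generate_parcel_table(cfg)
        assert parcels.n_parcels == 4
        adj = parcels.adjacency_matrix()
        assert adj[:2, :2].sum() == 2  # one undirected edge
        assert adj[2:, 2:].sum() == 2

    def test_same_seed_identical_tables(self, tmp_path):
        from axoncalib import io as cio

        cfg = axc.GeneratorConfig(n_parcels_per_hemisphere=8, seed=9)
        for k in range(2):
            cio.write_parcel_table(
                axc.generate_parcel_table(cfg), tmp_path / f"p{k}.tsv"
            )
        assert (tmp_path / "p0.tsv").read_bytes() == (tmp_path / "p1.tsv").read_bytes()

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigError, match="edr_lambda"):
            axc.GeneratorConfig(edr_lambda=-0.1)
        with pytest.raises(ConfigError, match="length_range"):
            axc.GeneratorConfig(length_range=(50.0, 20.0))


class TestLengthMatrix:
    def test_symmetry_zero_diagonal_and_range(self, default_cohort):
        cfg, parcels, lengths, _, _ = default_cohort
        assert np.allclose(lengths, lengths.T)
        assert np.all(np.diag(lengths) == 0)
        off = lengths[pair_indices(parcels.n_parcels)]
        lo, hi = cfg.length_range
        assert off.min() >= lo and off.max() <= hi

    def test_interhemispheric_longer_on_average(self, default_cohort):
        _, parcels, lengths, _, _ = default_cohort
        masks = pair_class_masks(parcels)
        off = lengths[pair_indices(parcels.n_parcels)]
        assert off[masks["inter"]].mean() > off[masks["intra"]].mean()

    def test_adjacent_pairs_get_short_lengths(self, default_cohort):
        _, parcels, lengths, _, _ = default_cohort
        masks = pair_class_masks(parcels)
        off = lengths[pair_indices(parcels.n_parcels)]
        assert off[masks["adjacent"]].mean() < off[masks["intra_nonadjacent"]].mean()

    def test_mismatched_parcels_rejected(self):
        cfg_a = axc.GeneratorConfig(n_parcels_per_hemisphere=5, seed=0)
        cfg_b = axc.GeneratorConfig(n_parcels_per_hemisphere=6, seed=0)
        parcels = axc.generate_parcel_table(cfg_a)
        with pytest.raises(ConfigError):
            axc.generate_length_matrix(parcels, cfg_b)


class TestCohort:
    def test_subject_matrices_valid(self, default_cohort):
        _, parcels, _, subjects, _ = default_cohort
        for sub in subjects[:3]:
            m = sub.streamlines
            assert np.allclose(m, m.T)
            assert np.all(np.diag(m) == 0)
            assert (m >= 0).all()
            assert sub.callosal_area > 0
            assert sub.sex in ("F", "M")

    def test_callosal_areas_near_configured_mean(self):
        cfg = axc.GeneratorConfig(n_parcels_per_hemisphere=20, n_subjects=40, seed=21)
        _, _, subjects, _ = axc.generate_default_cohort(cfg)
        areas = np.array([s.callosal_area for s in subjects])
        # cohort mean within 4 standard errors of the configured mean
        se = areas.std(ddof=1) / np.sqrt(len(areas))
        assert abs(areas.mean() - cfg.callosal_area_mean) < 4 * max(se, 1.0)

    def test_noise_free_limit_deterministic_in_length(self, noise_free_cohort):
        cfg, parcels, lengths, subjects, manifest = noise_free_cohort
        iu = pair_indices(parcels.n_parcels)
        expected = manifest.base_scale * np.exp(-cfg.edr_lambda * lengths[iu])
        for sub in subjects:
            assert np.allclose(sub.streamlines[iu], expected, rtol=1e-12)

    def test_edr_slope_recovered_within_bootstrap_ci(self):
        cfg = axc.GeneratorConfig(n_parcels_per_hemisphere=24, n_subjects=50, seed=13)
        parcels, lengths, subjects, _ = axc.generate_default_cohort(cfg)
        mean = axc.mean_streamline_matrix(subjects)
        slope, (lo, hi) = axc.edr_slope(mean, lengths, parcels, n_boot=400, seed=3)
        assert lo <= -cfg.edr_lambda <= hi

    def test_intra_inter_decay_parity_by_construction(self, default_cohort):
        _, parcels, lengths, subjects, _ = default_cohort
        mean = axc.mean_streamline_matrix(subjects)
        iu = pair_indices(parcels.n_parcels)
        masks = pair_class_masks(parcels)
        slopes = {}
        for cls in ("intra_nonadjacent", "inter"):
            lens = lengths[iu][masks[cls]]
            vals = np.log(mean[iu][masks[cls]])
            slopes[cls] = scipy.stats.linregress(lens, vals)
        a, b = slopes["intra_nonadjacent"], slopes["inter"]
        z = (a.slope - b.slope) / np.hypot(a.stderr, b.stderr)
        assert abs(z) < 4

    def test_log_weights_approximately_normal_over_nonadjacent_pairs(self):
        rejections = 0
        for seed in range(5):
            cfg = axc.GeneratorConfig(n_parcels_per_hemisphere=45, n_subjects=1,
                                      seed=seed)
            parcels, lengths, subjects, _ = axc.generate_default_cohort(cfg)
            iu = pair_indices(parcels.n_parcels)
            masks = pair_class_masks(parcels)
            v = np.log(subjects[0].streamlines[iu][masks["intra_nonadjacent"]])
            sub = np.random.default_rng(seed).choice(v, 500, replace=False)
            if scipy.stats.shapiro(sub).pvalue < 0.01:
                rejections += 1
        assert rejections <= 1

    def test_adjacency_boost_raises_adjacent_weights(self, default_cohort):
        _, parcels, lengths, subjects, _ = default_cohort
        mean = axc.mean_streamline_matrix(subjects)
        iu = pair_indices(parcels.n_parcels)
        masks = pair_class_masks(parcels)
        # compare log-residuals after removing the length trend
        lens, vals = lengths[iu], np.log(mean[iu])
        fit = scipy.stats.linregress(
            lens[masks["intra_nonadjacent"]], vals[masks["intra_nonadjacent"]]
        )
        resid = vals - (fit.intercept + fit.slope * lens)
        assert resid[masks["adjacent"]].mean() > resid[masks["intra_nonadjacent"]].mean() + 0.5

    def test_manifest_records_ground_truth(self, default_cohort):
        cfg, _, subjects, = default_cohort[0], default_cohort[1], default_cohort[3]
        manifest = default_cohort[4]
        assert manifest.true_axons_per_streamline == cfg.true_axons_per_streamline
        truth = manifest.true_axon_matrix(subjects[0])
        assert np.allclose(truth, cfg.true_axons_per_streamline * subjects[0].streamlines)

    def test_same_seed_identical_cohort_bytes(self, tmp_path):
        cfg = axc.GeneratorConfig(n_parcels_per_hemisphere=6, n_subjects=3, seed=17)
        digests = []
        for k in range(2):
            parcels, lengths, subjects, manifest = axc.generate_default_cohort(cfg)
            out = tmp_path / f"cohort{k}"
            axc.write_cohort(out, parcels, lengths, subjects, manifest)
            digests.append(sorted(
                (p.relative_to(out).as_posix(), p.read_bytes())
                for p in out.rglob("*") if p.is_file()
            ))
        assert digests[0] == digests[1]
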