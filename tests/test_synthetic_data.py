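"""Toy atlas, lesion generator, planted response model, cohort assembly."""

from dataclasses import replace

import numpy as np
import pytest

import lesionpls as lp
from lesionpls.synthetic_data import (
    make_lesions,
    make_toy_atlas,
    plant_region_weights,
    region_centroids,
    territory_mask,
)


SMALL = lp.GeneratorConfig(grid_shape=(10, 10, 10), n_regions=12,
                           blob_size_range=(40, 80), seed=3)


class TestToyAtlas:
    def test_regions_partition_the_grid(self):
        atlas = make_toy_atlas(SMALL)
        total = np.zeros(SMALL.grid_shape, dtype=int)
        for r in atlas:
            total += r.membership.astype(int)
        assert np.all(total == 1)

    def test_deterministic_given_seed(self):
        a = make_toy_atlas(SMALL)
        b = make_toy_atlas(SMALL)
        for ra, rb in zip(a, b):
            assert ra.region_id == rb.region_id
            assert np.array_equal(ra.membership, rb.membership)

    def test_one_region_per_voxel_degenerate_case(self):
        cfg = lp.GeneratorConfig(grid_shape=(2, 2, 2), n_regions=8,
                                 blob_size_range=(1, 2), seed=0)
        atlas = make_toy_atlas(cfg)
        assert len(atlas) == 8
        for r in atlas:
            assert r.membership.sum() == 1

    def test_overlap_regions_are_dilated_duplicates(self):
        cfg = replace(SMALL, n_overlap_regions=2)
        atlas = make_toy_atlas(cfg)
        regions = list(atlas)
        assert len(regions) == SMALL.n_regions + 2
        for i in range(2):
            base, dup = regions[i], regions[SMALL.n_regions + i]
            assert dup.region_id == base.region_id + "-b"
            assert dup.atlas_id == "toy-b"
            assert np.all(dup.membership[base.membership.astype(bool)])
            assert dup.membership.sum() > base.membership.sum()


class TestLesions:
    def test_lesions_confined_to_territory(self):
        masks, _ = make_lesions(SMALL)
        allowed = territory_mask(SMALL)
        for m in masks:
            assert not np.any(m.voxel_grid.astype(bool) & ~allowed)

    def test_blob_volumes_within_configured_range(self):
        cfg = replace(SMALL, n_blobs_range=(1, 1))
        masks, _ = make_lesions(cfg)
        lo, hi = cfg.blob_size_range
        for m in masks:
            assert lo <= m.voxel_grid.sum() <= hi

    def test_zero_size_blobs_give_empty_masks(self):
        cfg = replace(SMALL, blob_size_range=(0, 0))
        masks, seeds = make_lesions(cfg)
        assert len(seeds) == cfg.n_patients
        for m in masks:
            assert m.voxel_grid.sum() == 0

    def test_walk_blobs_are_contiguous(self):
        cfg = replace(SMALL, n_blobs_range=(1, 1))
        masks, _ = make_lesions(cfg)
        from scipy.ndimage import label

        for m in masks:
            _, n_components = label(m.voxel_grid)
            assert n_components == 1

    def test_sphere_shape_supported(self):
        cfg = replace(SMALL, lesion_shape="sphere", n_blobs_range=(1, 1))
        masks, _ = make_lesions(cfg)
        lo, hi = cfg.blob_size_range
        assert all(lo <= m.voxel_grid.sum() <= hi for m in masks)

    def test_tube_seeding_keeps_seeds_near_territory_axis(self):
        cfg = replace(SMALL, blob_seed_spread=0.5, n_patients=30)
        _, seeds = make_lesions(cfg)
        xs = np.array([s[0] for s in seeds])
        x_max = cfg.grid_shape[0] * cfg.territory_fraction
        assert np.all(np.abs(xs - x_max / 2) <= 3.0)


class TestPlantedWeights:
    def test_harmful_zone_negative_elsewhere_zero(self):
        atlas = make_toy_atlas(SMALL)
        region_ids = [r.region_id for r in atlas]
        planted = plant_region_weights(SMALL, atlas, region_ids)
        cent = region_centroids(atlas)
        y_cut = SMALL.grid_shape[1] * SMALL.harmful_zone_fraction
        for rid in region_ids:
            if cent.loc[rid, "y"] < y_cut:
                assert planted[rid] < 0
                assert abs(planted[rid]) == pytest.approx(
                    abs(SMALL.harmful_weight), rel=0.21)
            else:
                assert planted[rid] == 0.0


class TestMakeCohort:
    def test_out_of_territory_regions_pruned(self, default_synthetic):
        syn = default_synthetic
        assert len(syn.dropped_region_ids) > 0
        all_ids = {r.region_id for r in syn.atlas}
        assert set(syn.loads.columns) | set(syn.dropped_region_ids) == all_ids
        assert np.all(syn.loads.to_numpy().sum(axis=0) > 0)  # no all-zero column kept

    def test_reproducible_and_seed_sensitive(self):
        a = lp.make_cohort(SMALL)
        b = lp.make_cohort(SMALL)
        c = lp.make_cohort(replace(SMALL, seed=SMALL.seed + 1))
        assert a.loads.equals(b.loads)
        assert np.array_equal(a.cohort.response, b.cohort.response)
        assert a.blob_seeds == b.blob_seeds
        assert not np.array_equal(a.cohort.response, c.cohort.response)

    def test_hours_clipped_and_near_configured_mean(self, default_synthetic):
        cfg = default_synthetic.config
        hours = default_synthetic.cohort.blocks["hours"]["therapy_hours"].to_numpy()
        assert hours.min() >= 1.0
        tol = 3 * cfg.hours_sd / np.sqrt(cfg.n_patients)
        assert abs(hours.mean() - cfg.hours_mean) <= tol

    def test_noiseless_cohort_response_equals_planted_model(self):
        syn = lp.make_cohort(replace(SMALL, noise_sd=0.0))
        assert np.array_equal(syn.cohort.response, syn.noiseless_response)
        hours = syn.cohort.blocks["hours"]["therapy_hours"].to_numpy()
        cfg = syn.config
        expected = (
            cfg.response_intercept
            + syn.loads.to_numpy() @ syn.planted_weights.to_numpy()
            + cfg.beta_hours * hours
        )
        assert np.allclose(syn.cohort.response, expected)

    def test_default_noise_is_ten_percent_of_signal_sd(self, default_synthetic):
        syn = default_synthetic
        residual = syn.cohort.response - syn.noiseless_response
        target_sd = 0.1 * np.std(syn.noiseless_response, ddof=1)
        # 18 draws: sd estimate is loose, check the right order of magnitude
        assert 0.4 * target_sd < residual.std(ddof=1) < 2.0 * target_sd

    def test_full_components_recover_noiseless_response_in_sample(self):
        syn = lp.make_cohort(replace(SMALL, noise_sd=0.0))
        model = lp.fit_model(syn.cohort, lp.ModelSpec(("hours", "lesions"), 50))
        scale = np.std(syn.cohort.response)
        assert np.allclose(model.fitted_values, syn.cohort.response,
                           atol=1e-6 * scale)

    def test_block_shapes_and_names(self, default_synthetic):
        cohort = default_synthetic.cohort
        cfg = default_synthetic.config
        assert set(cohort.blocks) == {"demographics", "initial", "hours",
                                      "behavioural", "lesions"}
        assert cohort.blocks["behavioural"].shape == (cfg.n_patients, cfg.n_behavioural)
        assert cohort.blocks["hours"].shape == (cfg.n_patients, 1)

    def test_neighbouring_loads_correlate_more_than_distant_ones(self):
        syn = lp.make_cohort(replace(SMALL, n_patients=40, seed=11))
        loads = syn.loads
        cent = region_centroids(syn.atlas).loc[list(loads.columns)]
        corr = loads.corr().to_numpy()
        pos = cent[["x", "y", "z"]].to_numpy()
        dist = np.sqrt(((pos[:, None] - pos[None, :]) ** 2).sum(axis=2))
        iu = np.triu_indices(len(loads.columns), k=1)
        near = dist[iu] < np.percentile(dist[iu], 25)
        far = dist[iu] > np.percentile(dist[iu], 75)
        assert corr[iu][near].mean() > corr[iu][far].mean()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            lp.GeneratorConfig(n_patients=1)
        with pytest.raises(ValueError):
            lp.GeneratorConfig(noise_sd=-1.0)
        with pytest.raises(ValueError):
            lp.GeneratorConfig(grid_shape=(2, 2, 2), n_regions=9)
        with pytest.raises(ValueError):
            lp.GeneratorConfig(lesion_shape="cube")

    def test_seed_override_argument(self):
        a = lp.make_cohort(SMALL, seed=99)
        b = lp.make_cohort(replace(SMALL, seed=99))
        assert np.array_equal(a.cohort.response, b.cohort.response)
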