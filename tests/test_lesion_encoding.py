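"""Lesion-load encoding: binarisation, overlap fractions, cohort matrices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lesionpls as lp
from lesionpls.lesion_encoding import region_manifest_table


def brute_force_load(mask_grid, region_grid):
    """Voxel-by-voxel counting oracle for the overlap fraction."""
    shared = 0
    total = 0
    it = np.nditer(region_grid, flags=["multi_index"])
    for v in it:
        if v:
            total += 1
            if mask_grid[it.multi_index]:
                shared += 1
    return shared / total


class TestBinarize:
    def test_all_zero_map_stays_zero(self):
        out = lp.binarize_probabilistic_region(np.zeros((3, 3, 3)))
        assert not out.any()

    def test_threshold_boundary_is_inclusive(self):
        m = np.array([0.49, 0.50, 0.51]).reshape(1, 1, 3)
        assert lp.binarize_probabilistic_region(m, 0.5).ravel().tolist() == [0, 1, 1]

    def test_matches_elementwise_comparison(self, rng):
        m = rng.random((5, 5, 5))
        out = lp.binarize_probabilistic_region(m, 0.5)
        for idx in np.ndindex(5, 5, 5):
            assert out[idx] == (1 if m[idx] >= 0.5 else 0)

    def test_rejects_out_of_range_probabilities(self):
        with pytest.raises(ValueError):
            lp.binarize_probabilistic_region(np.full((2, 2, 2), 1.5))


class TestLesionLoad:
    def test_full_overlap_is_one(self):
        region = np.zeros((3, 3, 3))
        region[0, :, :] = 1
        mask = lp.LesionMask("p", np.ones((3, 3, 3)))
        assert lp.lesion_load(mask, region) == 1.0

    def test_empty_lesion_is_zero(self):
        region = np.ones((2, 2, 2))
        mask = lp.LesionMask("p", np.zeros((2, 2, 2)))
        assert lp.lesion_load(mask, region) == 0.0

    def test_matches_voxel_counting_oracle(self, rng):
        region = np.zeros((4, 4, 4), dtype=int)
        flat = rng.choice(64, size=8, replace=False)
        region.ravel()[flat] = 1
        for _ in range(5):
            mask_grid = (rng.random((4, 4, 4)) < 0.4).astype(int)
            mask = lp.LesionMask("p", mask_grid)
            assert lp.lesion_load(mask, region) == pytest.approx(
                brute_force_load(mask_grid, region)
            )

    def test_empty_region_is_an_error(self):
        mask = lp.LesionMask("p", np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="no member voxels"):
            lp.lesion_load(mask, np.zeros((2, 2, 2)))

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**24 - 1))
    def test_monotone_under_added_lesion_voxels(self, seed):
        r = np.random.default_rng(seed)
        region = (r.random((4, 4, 4)) < 0.5).astype(int)
        if not region.any():
            region[0, 0, 0] = 1
        small = (r.random((4, 4, 4)) < 0.3).astype(int)
        extra = np.clip(small + (r.random((4, 4, 4)) < 0.3), 0, 1)
        load_small = lp.lesion_load(lp.LesionMask("p", small), region)
        load_big = lp.lesion_load(lp.LesionMask("p", extra), region)
        assert load_big >= load_small

    def test_integer_voxel_count_recovery(self, rng):
        # load × region size must recover the exact shared-voxel count
        region = (rng.random((5, 5, 5)) < 0.5).astype(int)
        mask_grid = (rng.random((5, 5, 5)) < 0.5).astype(int)
        load = lp.lesion_load(lp.LesionMask("p", mask_grid), region)
        n_shared = load * region.sum()
        assert n_shared == pytest.approx(round(n_shared), abs=1e-12)


def toy_region_set(n_regions=5, shape=(4, 4, 5)):
    regions = []
    for i in range(n_regions):
        membership = np.zeros(shape, dtype=int)
        membership[:, :, i] = 1
        regions.append(lp.Region(f"R{i}", "atlasA", membership))
    return lp.RegionSet(tuple(regions), space_tag="toy")


class TestEncodeCohort:
    def test_untouched_region_is_pruned_and_recorded(self):
        rs = toy_region_set()
        masks = []
        for i in range(3):
            g = np.zeros((4, 4, 5), dtype=int)
            g[i, :, :3] = 1  # never touches slab 3 or 4
            masks.append(lp.LesionMask(f"P{i}", g, space_tag="toy"))
        out = lp.encode_cohort(masks, rs, drop_zero_variance=True)
        assert out.region_ids == ("R0", "R1", "R2")
        assert out.dropped_region_ids == ("R3", "R4")

    def test_no_pruning_when_every_region_touched(self):
        rs = toy_region_set()
        g = np.ones((4, 4, 5), dtype=int)
        masks = [lp.LesionMask("P0", g, space_tag="toy"),
                 lp.LesionMask("P1", np.zeros((4, 4, 5), dtype=int), space_tag="toy")]
        out = lp.encode_cohort(masks, rs)
        assert out.dropped_region_ids == ()
        assert len(out.region_ids) == 5

    def test_matrix_equals_rowwise_lesion_load_calls(self, default_synthetic):
        syn = default_synthetic
        masks, _ = lp.make_lesions(syn.config)
        out = lp.encode_cohort(masks, syn.atlas, drop_zero_variance=False)
        regions = {r.region_id: r.membership for r in syn.atlas}
        for i, m in enumerate(masks[:4]):
            for j, rid in enumerate(out.region_ids):
                assert out.values[i, j] == pytest.approx(
                    lp.lesion_load(m, regions[rid]))

    def test_permutation_equivariance(self):
        rs = toy_region_set()
        rng = np.random.default_rng(3)
        masks = [lp.LesionMask(f"P{i}", (rng.random((4, 4, 5)) < 0.3).astype(int),
                               space_tag="toy") for i in range(6)]
        out = lp.encode_cohort(masks, rs, drop_zero_variance=False)
        perm = rng.permutation(6)
        out_p = lp.encode_cohort([masks[i] for i in perm], rs, drop_zero_variance=False)
        assert np.array_equal(out_p.values, out.values[perm])
        assert out_p.patient_ids == tuple(out.patient_ids[i] for i in perm)

    def test_space_mismatch_names_patient(self):
        rs = toy_region_set()
        masks = [lp.LesionMask("P0", np.zeros((4, 4, 5), dtype=int), space_tag="toy"),
                 lp.LesionMask("Pbad", np.zeros((4, 4, 5), dtype=int), space_tag="other")]
        with pytest.raises(ValueError, match="Pbad"):
            lp.encode_cohort(masks, rs)

    def test_all_loads_in_unit_interval(self, default_synthetic):
        v = default_synthetic.loads.to_numpy()
        assert v.min() >= 0 and v.max() <= 1


class TestNiftiRoundTrip:
    def test_encode_via_nifti_files(self, tmp_path):
        nib = pytest.importorskip("nibabel")
        import pandas as pd
        from lesionpls.lesion_encoding import load_mask_nifti, load_region_set

        shape = (6, 6, 6)
        rng = np.random.default_rng(0)
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        rows = []
        for i in range(3):
            prob = np.zeros(shape)
            prob[2 * i : 2 * i + 2] = rng.random((2, 6, 6))
            path = tmp_path / f"region{i}.nii"
            nib.save(nib.Nifti1Image(prob, affine), str(path))
            rows.append({"region_id": f"reg{i}", "atlas_id": "A", "path": path.name})
        manifest = tmp_path / "manifest.tsv"
        pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)

        mask_grid = (rng.random(shape) < 0.5).astype(np.int16)
        nib.save(nib.Nifti1Image(mask_grid, affine), str(tmp_path / "P0.nii"))

        rs = load_region_set(manifest, threshold=0.5, space_tag="t")
        mask = load_mask_nifti(tmp_path / "P0.nii", space_tag="t")
        assert mask.patient_id == "P0"
        assert mask.voxel_volume == pytest.approx(8.0)
        out = lp.encode_cohort([mask], rs, drop_zero_variance=False)
        for j, r in enumerate(rs):
            assert out.values[0, j] == pytest.approx(
                brute_force_load(mask_grid, r.membership))
        table = region_manifest_table(rs)
        assert list(table.columns) == ["region_id", "atlas_id", "n_voxels"]
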