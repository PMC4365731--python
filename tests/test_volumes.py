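"""NIfTI masks, sphere ROIs, splits and pattern extraction."""

import struct

import nibabel as nib
import numpy as np
import pytest

from gramrsa.volumes import (
    EmptyMaskError,
    ROIMask,
    VolumeError,
    VoxelGrid,
    extract_patterns,
    make_sphere_roi,
    read_mask,
    read_roi_catalogue,
    split_anterior_posterior,
    write_mask,
)


@pytest.fixture()
def grid():
    # 3 mm isotropic grid symmetric about x = 0 (world spans +-60 mm in x)
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    affine[:3, 3] = (-60.0, -45.0, -24.0)
    return VoxelGrid(shape=(41, 31, 17), affine=affine)


class TestMaskIO:
    def test_round_trip(self, grid, tmp_path):
        rng = np.random.default_rng(3)
        vox = rng.integers(0, 15, size=(7, 3))
        vox = np.unique(vox, axis=0)
        mask = ROIMask(grid=grid, voxels=vox, roi_id="toy")
        path = tmp_path / "toy.nii.gz"
        write_mask(mask, path)
        loaded = read_mask(path)
        assert loaded.n_voxels == mask.n_voxels
        assert np.array_equal(loaded.voxels, mask.voxels)
        assert np.allclose(loaded.grid.affine, grid.affine)

    def test_threshold_and_count(self, grid, tmp_path):
        arr = np.zeros((10, 10, 10), dtype=np.float32)
        arr[[0, 1, 2, 3, 4, 5, 6], 5, 5] = 1.0
        img = nib.Nifti1Image(arr, affine=np.eye(4))
        path = tmp_path / "seven.nii"
        nib.save(img, path)
        assert read_mask(path).n_voxels == 7

    def test_empty_mask_rejected(self, tmp_path):
        img = nib.Nifti1Image(np.zeros((5, 5, 5), np.float32), np.eye(4))
        path = tmp_path / "empty.nii"
        nib.save(img, path)
        with pytest.raises(EmptyMaskError):
            read_mask(path)

    def test_non_3d_rejected(self, tmp_path):
        img = nib.Nifti1Image(np.zeros((4, 4, 4, 2), np.float32), np.eye(4))
        path = tmp_path / "fourd.nii"
        nib.save(img, path)
        with pytest.raises(VolumeError):
            read_mask(path)


class TestSphereROI:
    def test_radius_zero_at_voxel_center(self, grid):
        center = grid.world_coords(np.array([20, 15, 8]))
        roi = make_sphere_roi(center, 0.0, grid)
        assert roi.n_voxels == 1
        assert np.array_equal(roi.voxels[0], [20, 15, 8])

    def test_matches_exhaustive_scan(self, grid):
        center, radius = (0.0, 0.0, 0.0), 10.0
        roi = make_sphere_roi(center, radius, grid)
        # brute-force oracle: loop over every voxel with plain arithmetic
        count = 0
        a = grid.affine
        for i in range(grid.shape[0]):
            for j in range(grid.shape[1]):
                for k in range(grid.shape[2]):
                    x = a[0, 0] * i + a[0, 3]
                    y = a[1, 1] * j + a[1, 3]
                    z = a[2, 2] * k + a[2, 3]
                    if x * x + y * y + z * z <= radius * radius:
                        count += 1
        assert roi.n_voxels == count

    def test_fop_mirror_symmetry(self, grid):
        lh = make_sphere_roi((-36.0, 20.0, -3.0), 10.0, grid)
        rh = make_sphere_roi((36.0, 20.0, -3.0), 10.0, grid)
        assert lh.n_voxels == rh.n_voxels
        # mirrored voxel x-indices about the grid's x-centre (index 20)
        assert np.array_equal(
            np.sort(40 - lh.voxels[:, 0]), np.sort(rh.voxels[:, 0])
        )

    def test_translation_by_whole_voxels(self, grid):
        base = make_sphere_roi((0.0, 0.0, 0.0), 7.0, grid)
        shifted = make_sphere_roi((6.0, -3.0, 3.0), 7.0, grid)
        assert shifted.n_voxels == base.n_voxels
        assert np.array_equal(
            shifted.voxels, base.voxels + np.array([2, -1, 1])
        )

    def test_sphere_off_grid_rejected(self, grid):
        with pytest.raises(EmptyMaskError):
            make_sphere_roi((500.0, 500.0, 500.0), 5.0, grid)


class TestAnteriorPosteriorSplit:
    def test_partition_at_median(self, grid):
        roi = make_sphere_roi((0.0, 0.0, 0.0), 12.0, grid, roi_id="STG")
        ant, post = split_anterior_posterior(roi)
        assert ant.roi_id == "aSTG" and post.roi_id == "pSTG"
        merged = np.vstack([ant.voxels, post.voxels])
        assert merged.shape[0] == roi.n_voxels
        both = {tuple(v) for v in ant.voxels} & {tuple(v) for v in post.voxels}
        assert not both
        assert {tuple(v) for v in merged} == {tuple(v) for v in roi.voxels}

    def test_fixed_boundary(self, grid):
        roi = make_sphere_roi((0.0, 0.0, 0.0), 12.0, grid, roi_id="MTG")
        ant, post = split_anterior_posterior(roi, boundary_y_mm=0.0)
        assert np.all(ant.world_coords()[:, 1] > 0)
        assert np.all(post.world_coords()[:, 1] <= 0)

    def test_empty_half_rejected(self, grid):
        roi = make_sphere_roi((0.0, 0.0, 0.0), 12.0, grid, roi_id="ITG")
        with pytest.raises(EmptyMaskError, match="posterior"):
            split_anterior_posterior(roi, boundary_y_mm=-100.0)


def _write_condition_images(grid, values, mask, outdir, compress=False):
    """Write one 3-D image per condition with the pattern at mask voxels."""
    paths = {}
    suffix = ".nii.gz" if compress else ".nii"
    for k in range(values.shape[1]):
        arr = np.zeros(grid.shape, dtype=np.float32)
        arr[tuple(mask.voxels.T)] = values[:, k]
        path = outdir / f"cond{k}{suffix}"
        nib.save(nib.Nifti1Image(arr, grid.affine), path)
        paths[f"c{k}"] = path
    return paths


class TestExtractPatterns:
    def test_shape_and_values(self, grid, tmp_path):
        rng = np.random.default_rng(11)
        roi = make_sphere_roi((0.0, 0.0, 0.0), 9.0, grid, roi_id="blob")
        values = rng.normal(size=(roi.n_voxels, 12)).astype(np.float32)
        images = _write_condition_images(grid, values, roi, tmp_path)
        pm = extract_patterns(images, roi, subject_id="01",
                              condition_order=[f"c{k}" for k in range(12)])
        assert pm.values.shape == (roi.n_voxels, 12)
        assert np.allclose(pm.values, values, atol=1e-6)

    def test_direct_header_offset_read(self, grid, tmp_path):
        rng = np.random.default_rng(12)
        roi = make_sphere_roi((0.0, 0.0, 0.0), 6.0, grid, roi_id="blob")
        values = rng.normal(size=(roi.n_voxels, 12)).astype(np.float32)
        images = _write_condition_images(grid, values, roi, tmp_path)
        pm = extract_patterns(images, roi, condition_order=[f"c{k}" for k in range(12)])
        # independent reader: raw float32 at vox_offset + Fortran-order index
        raw = (tmp_path / "cond0.nii").read_bytes()
        vox_offset = int(struct.unpack_from("<f", raw, 108)[0])
        nx, ny = grid.shape[0], grid.shape[1]
        for row in (0, roi.n_voxels // 2, roi.n_voxels - 1):
            i, j, k = roi.voxels[row]
            off = vox_offset + 4 * (i + j * nx + k * nx * ny)
            val = struct.unpack_from("<f", raw, off)[0]
            assert pm.values[row, 0] == pytest.approx(val, abs=1e-6)

    def test_grid_mismatch_rejected(self, grid, tmp_path):
        roi = make_sphere_roi((0.0, 0.0, 0.0), 6.0, grid, roi_id="blob")
        arr = np.zeros((5, 5, 5), np.float32)
        path = tmp_path / "other.nii"
        nib.save(nib.Nifti1Image(arr, np.eye(4)), path)
        with pytest.raises(VolumeError):
            extract_patterns({"c0": path}, roi, condition_order=["c0"])

    def test_missing_condition_rejected(self, grid, tmp_path):
        rng = np.random.default_rng(13)
        roi = make_sphere_roi((0.0, 0.0, 0.0), 6.0, grid, roi_id="blob")
        values = rng.normal(size=(roi.n_voxels, 2)).astype(np.float32)
        images = _write_condition_images(grid, values, roi, tmp_path)
        with pytest.raises(VolumeError):
            extract_patterns(images, roi, condition_order=["c0", "c1", "c9"])

    def test_nonfinite_voxels_dropped(self, grid, tmp_path):
        rng = np.random.default_rng(14)
        roi = make_sphere_roi((0.0, 0.0, 0.0), 6.0, grid, roi_id="blob")
        values = rng.normal(size=(roi.n_voxels, 3)).astype(np.float32)
        values[2, 1] = np.nan
        images = _write_condition_images(grid, values, roi, tmp_path)
        pm = extract_patterns(images, roi,
                              condition_order=["c0", "c1", "c2"])
        assert pm.values.shape == (roi.n_voxels - 1, 3)
        assert np.all(np.isfinite(pm.values))


class TestROICatalogue:
    def test_mask_and_sphere_sources(self, grid, tmp_path):
        roi = make_sphere_roi((0.0, 0.0, 0.0), 7.0, grid, roi_id="blob")
        write_mask(roi, tmp_path / "blob.nii.gz")
        (tmp_path / "catalogue.tsv").write_text(
            "roi_id\themisphere\tsource_type\tsource\n"
            "L_blob\tL\tmask\tblob.nii.gz\n"
            "L_FOP\tL\tsphere\t-36,20,-3,10\n"
        )
        rois = read_roi_catalogue(tmp_path / "catalogue.tsv", grid=grid)
        assert [r.roi_id for r in rois] == ["L_blob", "L_FOP"]
        assert rois[0].n_voxels == roi.n_voxels
        assert rois[1].n_voxels == make_sphere_roi(
            (-36, 20, -3), 10, grid
        ).n_voxels
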