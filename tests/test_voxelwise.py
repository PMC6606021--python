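"""Voxel-wise driver, cluster thresholding and NIfTI round trips."""

import numpy as np
import pytest

from voxsem.fit import FitOptions, fit_model
from voxsem.growth import GrowthSpec
from voxsem.simulate import SyntheticConfig, generate_brain, generate_trajectories
from voxsem.voxelwise import (
    BrainImageSet,
    VoxelMapResult,
    VoxelwiseOptions,
    cluster_table,
    read_images,
    run_voxelwise,
    threshold_clusters,
    world_coordinates,
    write_maps,
)


def _result_from_z(z, affine=None, estimate=None):
    from scipy.stats import norm

    z = np.asarray(z, dtype=float)
    p = 2.0 * norm.sf(np.abs(z))
    est = z.copy() if estimate is None else estimate
    return VoxelMapResult(
        estimate=est, se=np.ones_like(z), z=z, p=p,
        affine=np.eye(4) if affine is None else affine,
        mask=np.isfinite(z), target="Sc", n_converged=int(np.isfinite(z).sum()),
    )


def _blob(shape, slices, z=6.0):
    vol = np.zeros(shape)
    vol[slices] = z
    return vol


class TestThresholdClusters:
    def test_no_signal_no_clusters(self):
        res = _result_from_z(np.zeros((10, 10, 10)))
        _, clusters = threshold_clusters(res)
        assert clusters == []

    def test_strict_extent_rule(self):
        """150-voxel blob survives k>100; 100- and 50-voxel blobs do not."""
        vol = np.zeros((12, 30, 12))
        vol[2:8, 1:6, 0:5] = 6.0     # 150 voxels
        vol[2:7, 9:14, 0:4] = 6.0    # 100 voxels
        vol[2:7, 17:22, 0:2] = 6.0   # 50 voxels
        _, clusters = threshold_clusters(_result_from_z(vol), k_min=100)
        assert [c.voxel_count for c in clusters] == [150]

    def test_corner_touching_blobs_split_by_connectivity(self):
        vol = np.zeros((8, 8, 8))
        vol[0:2, 0:2, 0:2] = 5.0
        vol[2:4, 2:4, 2:4] = 5.0  # touches only at the corner (1,1,1)-(2,2,2)
        _, c26 = threshold_clusters(_result_from_z(vol), k_min=0, connectivity=26)
        _, c6 = threshold_clusters(_result_from_z(vol), k_min=0, connectivity=6)
        assert len(c26) == 1
        assert len(c6) == 2

    def test_signs_reported_separately(self):
        vol = np.zeros((6, 6, 6))
        vol[0:3, :, :] = 5.0
        vol[4:6, :, :] = -5.0
        _, clusters = threshold_clusters(_result_from_z(vol), k_min=10)
        assert sorted(c.sign for c in clusters) == ["negative", "positive"]

    def test_peak_is_max_abs_z(self):
        vol = np.zeros((6, 6, 6))
        vol[1:4, 1:4, 1:4] = 5.0
        vol[2, 2, 2] = 9.0
        _, clusters = threshold_clusters(_result_from_z(vol), k_min=5)
        assert clusters[0].peak_voxel == (2, 2, 2)
        assert clusters[0].peak_z == 9.0

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError):
            threshold_clusters(_result_from_z(np.zeros((4, 4, 4))), connectivity=5)

    def test_matches_bruteforce_flood_fill(self, rng):
        """Component extents equal an independent BFS flood fill."""
        z = np.where(rng.random((15, 15, 15)) < 0.2, 6.0, 0.0)
        res = _result_from_z(z)
        _, clusters = threshold_clusters(res, k_min=0, connectivity=6)
        supra = z > 0
        seen = np.zeros_like(supra, dtype=bool)
        sizes = []
        for start in np.argwhere(supra):
            start = tuple(start)
            if seen[start]:
                continue
            stack, size = [start], 0
            seen[start] = True
            while stack:
                i, j, k = stack.pop()
                size += 1
                for d in ((1,0,0),(-1,0,0),(0,1,0),(0,-1,0),(0,0,1),(0,0,-1)):
                    nb = (i+d[0], j+d[1], k+d[2])
                    if all(0 <= nb[a] < 15 for a in range(3)) and supra[nb] and not seen[nb]:
                        seen[nb] = True
                        stack.append(nb)
            sizes.append(size)
        assert sorted(c.voxel_count for c in clusters) == sorted(sizes)

    def test_translation_invariance_of_extents_and_world_shift(self):
        vol = _blob((10, 10, 10), (slice(2, 6),) * 3)
        a1 = np.eye(4)
        a2 = np.eye(4); a2[:3, 3] = (5.0, -7.0, 2.0)
        _, c1 = threshold_clusters(_result_from_z(vol, affine=a1), k_min=10)
        _, c2 = threshold_clusters(_result_from_z(vol, affine=a2), k_min=10)
        assert c1[0].voxel_count == c2[0].voxel_count
        assert c1[0].peak_voxel == c2[0].peak_voxel
        np.testing.assert_allclose(
            np.subtract(c2[0].peak_world_mm, c1[0].peak_world_mm), (5.0, -7.0, 2.0)
        )


class TestWorldCoordinates:
    def test_identity(self):
        assert world_coordinates((3, 4, 5), np.eye(4)) == (3.0, 4.0, 5.0)

    def test_anisotropic_with_offset(self):
        aff = np.diag([-1.1, 1.1, 1.1, 1.0])
        aff[:3, 3] = (90.0, -126.0, -72.0)
        x, y, z = world_coordinates((10, 20, 30), aff)
        assert (x, y, z) == pytest.approx((90 - 11.0, -126 + 22.0, -72 + 33.0))

    def test_round_trip_through_inverse(self, rng):
        aff = np.eye(4)
        aff[:3, :3] = np.diag([1.1, 1.2, 0.9])
        aff[:3, 3] = rng.normal(size=3)
        vox = (4, 7, 2)
        world = world_coordinates(vox, aff)
        back = np.linalg.inv(aff) @ np.append(world, 1.0)
        np.testing.assert_allclose(back[:3], vox, atol=1e-12)

    def test_singular_affine_rejected(self):
        aff = np.zeros((4, 4))
        with pytest.raises(ValueError):
            world_coordinates((0, 0, 0), aff)


class TestImageIO:
    def test_write_read_round_trip(self, tmp_path, rng):
        shape = (6, 5, 4)
        z = rng.normal(size=shape)
        res = _result_from_z(z)
        paths = {k: tmp_path / f"{k}.nii" for k in ("estimate", "z", "p")}
        write_maps(res, paths)
        images = read_images([paths["z"]])
        np.testing.assert_allclose(images.data[0], z, atol=1e-6)  # float32 storage
        np.testing.assert_allclose(images.affine, np.eye(4))

    def test_mismatched_affines_rejected(self, tmp_path, rng):
        import nibabel as nib

        a = nib.Nifti1Image(rng.normal(size=(4, 4, 4)).astype(np.float32), np.eye(4))
        shifted = np.eye(4); shifted[0, 3] = 2.0
        b = nib.Nifti1Image(rng.normal(size=(4, 4, 4)).astype(np.float32), shifted)
        nib.save(a, tmp_path / "a.nii"); nib.save(b, tmp_path / "b.nii")
        with pytest.raises(ValueError, match="affine"):
            read_images([tmp_path / "a.nii", tmp_path / "b.nii"])

    def test_mask_restricts_analysis(self, tmp_path, rng):
        import nibabel as nib

        vols = rng.normal(size=(3, 4, 4, 4)).astype(np.float32)
        nib.save(nib.Nifti1Image(np.moveaxis(vols, 0, -1), np.eye(4)), tmp_path / "d.nii")
        mask = np.zeros((4, 4, 4), dtype=np.uint8); mask[:2] = 1
        nib.save(nib.Nifti1Image(mask, np.eye(4)), tmp_path / "m.nii")
        images = read_images([tmp_path / "d.nii"], mask_path=tmp_path / "m.nii")
        assert images.mask.sum() == 32


@pytest.fixture(scope="module")
def small_study():
    cfg = SyntheticConfig(
        n_subjects=120, image_dims=(5, 5, 5),
        effect_regions=(((2, 2, 2), 1.6, 2.5),), seed=31,
    )
    data, truth = generate_trajectories(cfg)
    images, regions = generate_brain(cfg, truth)
    spec = GrowthSpec()
    base = fit_model(data, spec, options=FitOptions(n_starts=1, compute_se=False, n_quad=5))
    return cfg, data, images, regions, spec, base


class TestRunVoxelwise:
    def test_misaligned_subject_axis_rejected(self, small_study):
        _, data, images, _, spec, _ = small_study
        short = BrainImageSet(images.data[:-5], images.affine, images.mask)
        with pytest.raises(ValueError, match="mismatch"):
            run_voxelwise(short, data, spec)

    def test_constant_voxel_skipped(self, small_study):
        _, data, images, _, spec, base = small_study
        arr = images.data.copy()
        arr[:, 0, 0, 0] = 3.7
        imgs = BrainImageSet(arr, images.affine, images.mask)
        res = run_voxelwise(
            imgs, data, spec, VoxelwiseOptions(n_quad=5), base_fit=base
        )
        assert np.isnan(res.estimate[0, 0, 0])
        assert res.n_skipped >= 1

    def test_planted_effect_detected_and_maps_consistent(self, small_study):
        _, data, images, regions, spec, base = small_study
        res = run_voxelwise(images, data, spec, VoxelwiseOptions(n_quad=5), base_fit=base)
        finite = np.isfinite(res.z)
        np.testing.assert_allclose(
            res.z[finite], (res.estimate / res.se)[finite], atol=1e-10
        )
        assert res.p[finite].min() >= 0 and res.p[finite].max() <= 1
        assert np.nanmean(res.z[regions[0]]) > 3.0
        # out-of-sphere voxels share one smooth random field per subject,
        # so on a 5^3 volume they are strongly correlated: the mean null z
        # has few effective degrees of freedom and only a loose bound
        assert abs(np.nanmean(res.z[~regions[0]])) < 1.2

    def test_beta_mode_tracks_full_refit(self, small_study):
        """Audit: the fast scoring mode agrees with full per-voxel
        re-optimization of every parameter."""
        _, data, images, _, spec, base = small_study
        sub = BrainImageSet(
            images.data[:, :3, :2, :2], images.affine, images.mask[:3, :2, :2]
        )
        fast = run_voxelwise(sub, data, spec, VoxelwiseOptions(refit="beta", n_quad=5), base_fit=base)
        full = run_voxelwise(sub, data, spec, VoxelwiseOptions(refit="full", n_quad=5), base_fit=base)
        m = np.isfinite(fast.estimate) & np.isfinite(full.estimate)
        assert m.sum() >= 10
        np.testing.assert_allclose(fast.estimate[m], full.estimate[m], atol=0.05)

    def test_warm_and_cold_full_refits_agree(self, small_study):
        """Per-voxel full refits reach the same optimum whether started
        from the base fit or from automatic moment-based values."""
        from voxsem.growth import ParamPacker
        from voxsem.likelihood import marginal_loglik

        _, data, images, _, spec, base = small_study
        opts = FitOptions(n_starts=1, compute_se=False, n_quad=5, gtol=1e-7, ftol=1e-16, maxiter=5000)
        packer = ParamPacker(spec, len(data.covariate_names), has_voxel=True)
        flat = images.data.reshape(images.n_subjects, -1)
        for k in range(4):
            v = flat[:, k]
            v = (v - v.mean()) / v.std()
            vdata = data.with_voxel(v)
            warm_init = base.params.copy()
            warm_init.beta_voxel = 0.0
            warm = fit_model(vdata, spec, init=warm_init, options=opts)
            cold = fit_model(vdata, spec, init="auto", options=opts)
            assert warm.loglik == pytest.approx(cold.loglik, abs=1e-6)

    def test_voxel_order_invariance(self, small_study):
        _, data, images, _, spec, base = small_study
        res1 = run_voxelwise(images, data, spec, VoxelwiseOptions(n_quad=5, chunk=16), base_fit=base)
        res2 = run_voxelwise(images, data, spec, VoxelwiseOptions(n_quad=5, chunk=125), base_fit=base)
        np.testing.assert_allclose(res1.estimate, res2.estimate, atol=1e-9, equal_nan=True)

    def test_cluster_table_layout(self):
        vol = _blob((8, 8, 8), (slice(1, 5),) * 3)
        _, clusters = threshold_clusters(_result_from_z(vol), k_min=10)
        tab = cluster_table(clusters)
        assert list(tab.columns) == [
            "voxel_count", "peak_i", "peak_j", "peak_k",
            "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_z", "sign",
        ]
        assert tab["voxel_count"].iloc[0] == 64
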