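"""Sphere masks, eigenvariates, nuisance regression, ROI extraction."""

import numpy as np
import pytest

from chronodcm import preprocess as pp


def mni_affine(voxel_mm=4.0, shape=(48, 56, 48)):
    """A simple MNI-like affine centred on the grid."""
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -voxel_mm * (np.array(shape) - 1) / 2.0
    return aff


class TestSphereMask:
    def test_tiny_radius_on_voxel_centre_selects_one_voxel(self):
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        vox = pp.sphere_mask((4.0, 6.0, 8.0), 0.9, aff, (10, 10, 10))
        assert vox.shape == (1, 3)
        np.testing.assert_array_equal(vox[0], [2, 3, 4])

    def test_count_matches_lattice_enumeration(self):
        # 2 mm isotropic grid, 6 mm radius: voxel offsets with |d|^2 <= 3^2
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        vox = pp.sphere_mask((20.0, 20.0, 20.0), 6.0, aff, (21, 21, 21))
        count = sum(
            1
            for i in range(-3, 4)
            for j in range(-3, 4)
            for k in range(-3, 4)
            if i * i + j * j + k * k <= 9
        )
        assert len(vox) == count

    def test_translation_equivariance(self):
        aff = np.diag([3.0, 3.0, 3.0, 1.0])
        a = pp.sphere_mask((15.0, 15.0, 15.0), 5.0, aff, (30, 30, 30))
        b = pp.sphere_mask((18.0, 15.0, 15.0), 5.0, aff, (30, 30, 30))
        np.testing.assert_array_equal(
            np.sort(a[:, 0]) + 1, np.sort(b[:, 0])
        )
        np.testing.assert_array_equal(a[:, 1:], b[:, 1:])

    def test_sphere_outside_grid_rejected(self):
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        with pytest.raises(ValueError):
            pp.sphere_mask((500.0, 500.0, 500.0), 6.0, aff, (10, 10, 10))


class TestEigenvariate:
    def test_rank_one_block_recovers_the_course(self, rng):
        course = rng.standard_normal(100)
        weights = rng.uniform(0.5, 2.0, 7)
        block = np.outer(course, weights)
        got = pp.eigenvariate(block)
        ref = (course - course.mean()) / (course - course.mean()).std()
        np.testing.assert_allclose(got, ref, atol=1e-10)

    def test_single_voxel_returns_standardized_series(self, rng):
        x = rng.standard_normal(64)
        got = pp.eigenvariate(x[:, None])
        ref = (x - x.mean()) / (x - x.mean()).std()
        np.testing.assert_allclose(np.abs(got), np.abs(ref), atol=1e-10)

    def test_maximizes_explained_variance(self, rng):
        """Monte-Carlo oracle: no random unit projection explains more
        variance than the direction behind the eigenvariate."""
        block = rng.standard_normal((80, 12))
        block -= block.mean(axis=0)
        ev = pp.eigenvariate(block)
        # energy captured by projecting onto the (unit-variance) eigenvariate
        pc_energy = np.sum((block.T @ ev) ** 2)
        for _ in range(1000):
            w = rng.standard_normal(12)
            proj = block @ (w / np.linalg.norm(w))
            sd = proj.std()
            if sd == 0:
                continue
            rand_energy = np.sum((block.T @ (proj / sd)) ** 2)
            assert rand_energy <= pc_energy + 1e-9

    def test_constant_block_rejected(self):
        with pytest.raises(ValueError):
            pp.eigenvariate(np.ones((10, 3)))


class TestNuisanceRegress:
    def test_orthogonal_confounds_only_demean(self, rng):
        t = np.arange(128)
        series = np.cos(2 * np.pi * t / 16)[:, None] + 5.0
        conf = np.sin(2 * np.pi * t / 16)[:, None]  # orthogonal to the series
        resid = pp.nuisance_regress(series, conf)
        np.testing.assert_allclose(resid[:, 0], series[:, 0] - series.mean(), atol=1e-10)

    def test_series_equal_to_confound_vanishes(self, rng):
        conf = rng.standard_normal((100, 3))
        resid = pp.nuisance_regress(conf[:, [1]], conf)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_every_confound(self, rng):
        series = rng.standard_normal((200, 4))
        conf = rng.standard_normal((200, 5))
        resid = pp.nuisance_regress(series, conf)
        np.testing.assert_allclose(resid.T @ conf, 0.0, atol=1e-8)

    def test_projection_is_idempotent(self, rng):
        series = rng.standard_normal((150, 3))
        conf = rng.standard_normal((150, 6))
        once = pp.nuisance_regress(series, conf)
        twice = pp.nuisance_regress(once, conf)
        np.testing.assert_allclose(once, twice, atol=1e-10)

    def test_rank_deficient_design_names_columns(self, rng):
        base = rng.standard_normal((80, 2))
        conf = pp.ConfoundSet(
            matrix=np.hstack([base, base[:, [0]]]),
            names=["m1", "m2", "dup"],
        )
        with pytest.raises(ValueError, match="dup"):
            pp.nuisance_regress(rng.standard_normal((80, 1)), conf)


class TestExtractRoiSeries:
    def make_volume(self, rng, spec, series_per_roi, shape, noise=0.0):
        aff = mni_affine(4.0, shape)
        t = series_per_roi.shape[0]
        vol = noise * rng.standard_normal((*shape, t))
        for r, center in enumerate(spec.mni_centers):
            vox = pp.sphere_mask(center, spec.radius_mm, aff, shape)
            for v in vox:
                vol[v[0], v[1], v[2], :] += series_per_roi[:, r]
        # give the WM/CSF reference spheres independent signal
        for center in (pp.WM_COORD, pp.CSF_COORD):
            vox = pp.sphere_mask(center, 6.0, aff, shape)
            sig = rng.standard_normal(t)
            for v in vox:
                vol[v[0], v[1], v[2], :] += sig
        return vol, aff

    def test_known_signal_recovered(self, rng):
        spec = pp.NetworkSpec(
            roi_names=("A", "B"),
            mni_centers=((20.0, 0.0, 0.0), (-20.0, 10.0, 10.0)),
        )
        series = rng.standard_normal((300, 2))
        vol, aff = self.make_volume(rng, spec, series, (24, 24, 24), noise=0.01)
        got = pp.extract_roi_series(vol, aff, spec)
        assert got.shape == (300, 2)
        for r in range(2):
            assert abs(np.corrcoef(got[:, r], series[:, r])[0, 1]) > 0.99

    def test_default_network_gives_eight_ordered_columns(self, rng):
        spec = pp.default_network()
        series = rng.standard_normal((60, 8))
        vol, aff = self.make_volume(rng, spec, series, (48, 56, 48))
        got = pp.extract_roi_series(vol, aff, spec)
        assert got.shape == (60, 8)
        # each extracted column matches its own ROI best, in declared order
        for r in range(8):
            cors = [abs(np.corrcoef(got[:, r], series[:, k])[0, 1]) for k in range(8)]
            assert int(np.argmax(cors)) == r

    def test_confound_free_input_stable_under_zero_motion(self, rng):
        spec = pp.NetworkSpec(roi_names=("A",), mni_centers=((20.0, 0.0, 0.0),))
        series = rng.standard_normal((30, 1))
        vol, aff = self.make_volume(rng, spec, series, (24, 24, 24))
        a = pp.extract_roi_series(vol, aff, spec)
        b = pp.extract_roi_series(vol, aff, spec, motion=None)
        np.testing.assert_allclose(a, b)

    def test_empty_sphere_names_the_roi(self, rng):
        spec = pp.NetworkSpec(
            roi_names=("far",), mni_centers=((500.0, 0.0, 0.0),), radius_mm=6.0
        )
        vol = rng.standard_normal((24, 24, 24, 10))
        with pytest.raises(ValueError, match="far"):
            pp.extract_roi_series(vol, mni_affine(4.0, (24, 24, 24)), spec)


class TestNetworkSpec:
    def test_default_network_is_the_eight_node_set(self):
        spec = pp.default_network()
        assert spec.n_rois == 8
        assert spec.radius_mm == 6.0
        assert spec.roi_names[0] == "mPFC"
        assert spec.mni_centers[1] == (0.0, -52.0, 26.0)

    def test_json_roundtrip(self):
        spec = pp.default_network()
        again = pp.NetworkSpec.from_json(spec.to_json())
        assert again == spec
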