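"""Affine and deformable registration: synthetic-transform recovery."""

import numpy as np
import pytest
from scipy import ndimage

import pseudopet as pp
from pseudopet import registration as rg


@pytest.fixture(scope="module")
def smooth_subject():
    cfg = pp.PhantomConfig(shape=(32, 32, 16), mr_noise_sigma=0.0,
                           mr_bias_amplitude=0.0)
    subj = pp.sample_subject(3, cfg)
    # smooth the piecewise-constant MR so interpolation loss does not
    # dominate the registration error
    return subj, ndimage.gaussian_filter(subj.mr, 1.0)


@pytest.fixture(scope="module")
def synthetic_pair(smooth_subject):
    subj, fixed = smooth_subject
    true = rg._params_to_matrix(
        np.array([1.0, -1.5, 0.5, 3.0, 0.0, 0.0, 1.02]),
        0.5 * subj.voxel_size * np.array(subj.shape),
    )
    amap_true = rg.AffineMap(true, subj.voxel_size)
    moving = rg.apply_affine(amap_true.inverse(), fixed)
    return subj, fixed, moving, amap_true


class TestAffine:
    def test_identity_recovered_for_same_image(self, smooth_subject):
        subj, fixed = smooth_subject
        amap = rg.affine_register(fixed, fixed, voxel_size=subj.voxel_size)
        assert np.abs(amap.matrix - np.eye(4)).max() < 1e-3

    def test_rotation_scale_recovery_ncc(self, synthetic_pair):
        subj, fixed, moving, _ = synthetic_pair
        rec = rg.affine_register(moving, fixed, voxel_size=subj.voxel_size)
        assert rec.final_ncc >= 0.99
        assert rec.converged

    def test_composition_near_identity(self, synthetic_pair):
        subj, fixed, moving, amap_true = synthetic_pair
        rec = rg.affine_register(moving, fixed, voxel_size=subj.voxel_size)
        comp = rec.matrix @ np.linalg.inv(amap_true.matrix)
        idx = np.argwhere(subj.labels > 0)
        world = (idx + 0.5) * subj.voxel_size
        pts = np.c_[world, np.ones(len(world))]
        moved = (comp @ pts.T).T[:, :3]
        disp_vox = np.linalg.norm(moved - world, axis=1) / subj.voxel_size[0]
        assert disp_vox.max() < 0.5

    def test_singular_matrix_rejected(self):
        bad = np.eye(4)
        bad[0, 0] = 1e-12
        with pytest.raises(ValueError, match="singular"):
            rg.AffineMap(bad, (2.0, 2.0, 2.0))


class TestApplyAffine:
    def test_identity_map_is_exact(self, smooth_subject):
        subj, fixed = smooth_subject
        amap = rg.AffineMap.identity(subj.voxel_size)
        np.testing.assert_array_equal(rg.apply_affine(amap, fixed), fixed)

    def test_integer_translation_is_exact_shift(self, smooth_subject):
        subj, fixed = smooth_subject
        B = np.eye(4)
        B[0, 3] = 2 * subj.voxel_size[0]  # +2 voxels along x
        amap = rg.AffineMap(B, subj.voxel_size)
        out = rg.apply_affine(amap, fixed)
        np.testing.assert_allclose(out[2:], fixed[:-2], atol=1e-12)

    def test_round_trip_interior_error_small(self, smooth_subject):
        subj, fixed = smooth_subject
        fixed = ndimage.gaussian_filter(fixed, 1.5)  # genuinely smooth image
        B = rg._params_to_matrix(
            np.array([0.7, -0.3, 0.2, 2.0, 1.0, -1.5, 1.01]),
            0.5 * subj.voxel_size * np.array(subj.shape),
        )
        amap = rg.AffineMap(B, subj.voxel_size)
        rt = rg.apply_affine(amap, rg.apply_affine(amap, fixed,
                                                   direction="inverse"))
        interior = (slice(4, -4),) * 3
        err = (np.linalg.norm((rt - fixed)[interior])
               / np.linalg.norm(fixed[interior]))
        assert err < 0.02

    def test_text_round_trip(self, tmp_path, smooth_subject):
        subj, _ = smooth_subject
        B = rg._params_to_matrix(np.array([1, 2, 3, 4, 5, 6, 1.1]),
                                 np.zeros(3))
        amap = rg.AffineMap(B, subj.voxel_size)
        amap.save(tmp_path / "map.txt")
        back = rg.AffineMap.load(tmp_path / "map.txt", subj.voxel_size)
        np.testing.assert_allclose(back.matrix, amap.matrix, atol=1e-10)


class TestWarp:
    def test_zero_field_identity(self, smooth_subject):
        _, fixed = smooth_subject
        fld = rg.DeformationField(np.zeros((3, *fixed.shape)))
        np.testing.assert_allclose(rg.warp(fld, fixed), fixed, atol=1e-12)

    def test_constant_integer_displacement_is_shift(self, smooth_subject):
        _, fixed = smooth_subject
        disp = np.zeros((3, *fixed.shape))
        disp[1] = 3.0  # pull from +3 in y
        out = rg.warp(rg.DeformationField(disp), fixed)
        np.testing.assert_allclose(out[:, :-3], fixed[:, 3:], atol=1e-12)

    def test_sinusoidal_field_matches_analytic_warp(self):
        # smooth analytic image warped by a known smooth field
        n = 32
        xx, yy, zz = np.meshgrid(*(np.arange(n),) * 2, np.arange(16),
                                 indexing="ij")
        img = np.sin(xx / 5.0) * np.cos(yy / 7.0) + 0.1 * zz
        ux = 1.5 * np.sin(2 * np.pi * yy / n)
        disp = np.zeros((3, n, n, 16))
        disp[0] = ux
        warped = rg.warp(rg.DeformationField(disp), img)
        analytic = np.sin((xx + ux) / 5.0) * np.cos(yy / 7.0) + 0.1 * zz
        interior = (slice(2, -2),) * 3
        assert rg.ncc(warped[interior], analytic[interior]) >= 0.995

    def test_field_nifti_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        fld = rg.DeformationField(rng.standard_normal((3, 8, 8, 8)))
        fld.save(tmp_path / "field.nii")
        back = rg.DeformationField.load(tmp_path / "field.nii")
        np.testing.assert_allclose(back.displacement, fld.displacement,
                                   atol=1e-6)


@pytest.fixture(scope="module")
def training_set():
    cfg = pp.PhantomConfig(shape=(32, 32, 16))
    subjects = [pp.sample_subject(s, cfg) for s in range(4)]
    fixed = subjects[0].mr
    movers = [s.mr for s in subjects[1:]]
    return fixed, movers


class TestDeformableTraining:
    def test_seeded_determinism(self, training_set):
        fixed, movers = training_set
        a = rg.train_deformable(fixed, movers[:2], epochs=3, seed=1)
        b = rg.train_deformable(fixed, movers[:2], epochs=3, seed=1)
        assert a.training_log == b.training_log

    def test_more_epochs_better_ncc(self, training_set):
        fixed, movers = training_set
        short = rg.train_deformable(fixed, movers, epochs=1, seed=0,
                                    learning_rate=3e-3)
        long = rg.train_deformable(fixed, movers, epochs=30, seed=0,
                                   learning_rate=3e-3)
        def mean_ncc(model):
            vals = []
            for m in movers:
                f = rg.predict_deformation(model, fixed, m)
                vals.append(rg.ncc(fixed, rg.warp(f, m)))
            return np.mean(vals)

        assert mean_ncc(long) > mean_ncc(short)
        assert long.training_log[-1] <= long.training_log[0]

    def test_self_pair_field_small(self, training_set):
        fixed, movers = training_set
        model = rg.train_deformable(fixed, [fixed] + movers, epochs=20,
                                    seed=0, learning_rate=3e-3)
        fld = rg.predict_deformation(model, fixed, fixed)
        mean_mag = np.mean(np.linalg.norm(fld.displacement, axis=0))
        assert mean_mag < 0.5

    def test_prediction_deterministic_and_improving(self, training_set):
        fixed, movers = training_set
        model = rg.train_deformable(fixed, movers, epochs=25, seed=0,
                                    learning_rate=3e-3)
        f1 = rg.predict_deformation(model, fixed, movers[0])
        f2 = rg.predict_deformation(model, fixed, movers[0])
        np.testing.assert_array_equal(f1.displacement, f2.displacement)
        for m in movers:
            fld = rg.predict_deformation(model, fixed, m)
            assert rg.ncc(fixed, rg.warp(fld, m)) >= rg.ncc(fixed, m)

    def test_grid_mismatch_rejected(self, training_set):
        fixed, movers = training_set
        model = rg.train_deformable(fixed, movers, epochs=1, seed=0)
        with pytest.raises(ValueError, match="grid"):
            rg.predict_deformation(model, fixed[:16], movers[0][:16])


class TestDemonsEngine:
    def test_demons_improves_alignment(self, training_set):
        fixed, movers = training_set
        model = rg.train_deformable(fixed, movers, engine="demons")
        fld = rg.predict_deformation(model, fixed, movers[0])
        assert rg.ncc(fixed, rg.warp(fld, movers[0])) > rg.ncc(fixed, movers[0])
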