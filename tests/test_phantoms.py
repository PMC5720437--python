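import numpy as np
import pytest

from sparsecbct.phantoms import (DeformationParams, GridSpec, MU_AIR, MU_BONE,
                                 MU_SOFT, MU_WATER, PhantomSpec, Primitive,
                                 Volume, apply_deformation, apply_rigid,
                                 build_qa_phantom, build_rigid_anatomy,
                                 build_thoracic_anatomy)
from sparsecbct.quality import roi_stats
from sparsecbct.registration import extract_edges
from sparsecbct.transforms import RigidTransform


class TestVoxelization:
    def test_painters_order_last_primitive_wins(self):
        grid = GridSpec.cube(20, 2.0)
        spec = PhantomSpec("p", [
            Primitive("box", (0, 0, 0), (10, 10, 10), 1.0),
            Primitive("box", (0, 0, 0), (4, 4, 4), 2.0),
        ], grid)
        v = spec.voxelize()
        assert v.voxels[10, 10, 10] == 2.0
        assert v.voxels[10, 10, 13] == 1.0

    def test_rotated_box_contains_expected_points(self):
        p = Primitive("box", (0, 0, 0), (10, 2, 5), 1.0, rotation_deg=90)
        # after 90 deg z-rotation the long axis lies along y
        assert p.contains(np.array([[0, 9, 0]]))[0]
        assert not p.contains(np.array([[9, 0, 0]]))[0]


class TestQaPhantom:
    def test_uniform_roi_is_exact_background(self):
        vol, spec = build_qa_phantom()
        s = roi_stats(vol, spec, "uniform_center")
        assert s.mean == pytest.approx(MU_WATER)
        assert s.sd == 0.0

    def test_bar_width_definition(self):
        _, spec = build_qa_phantom()
        g7 = spec.annotations["lp_groups"]["7"]
        assert g7["bar_width_mm"] == pytest.approx(10.0 / 14.0)

    def test_insert_rois_disjoint_from_background_roi(self):
        vol, spec = build_qa_phantom()
        m_poly = spec.roi_mask(vol, "polystyrene")
        m_ldpe = spec.roi_mask(vol, "LDPE")
        m_bg = spec.roi_mask(vol, "lc_background")
        assert not (m_poly & m_ldpe).any()
        assert not (m_poly & m_bg).any()

    def test_grid_too_small_raises(self):
        with pytest.raises(ValueError, match="too small"):
            build_qa_phantom(GridSpec.cube(40, 1.0))


class TestRigidAnatomies:
    def test_same_seed_bit_identical(self):
        grid = GridSpec.cube(64, 3.0)
        a = build_rigid_anatomy("head", seed=5, grid=grid)
        b = build_rigid_anatomy("head", seed=5, grid=grid)
        assert np.array_equal(a.voxels, b.voxels)
        c = build_rigid_anatomy("head", seed=6, grid=grid)
        assert not np.array_equal(a.voxels, c.voxels)

    @pytest.mark.parametrize("site", ["head", "pelvis"])
    def test_air_soft_bone_modes_present(self, site):
        v = build_rigid_anatomy(site, seed=1, grid=GridSpec.cube(80, 2.5))
        frac_air = np.mean(v.voxels == MU_AIR)
        frac_bone = np.mean(v.voxels >= 0.9 * MU_BONE)
        frac_soft = np.mean(np.abs(v.voxels - MU_SOFT) < 0.1 * MU_SOFT)
        assert frac_air > 0.1      # surrounding + cavities
        assert frac_bone > 0.005
        assert frac_soft > 0.1

    def test_bone_edges_exist_under_default_threshold(self, head_volume):
        assert len(extract_edges(head_volume)) > 0

    def test_unknown_site_raises(self):
        with pytest.raises(ValueError):
            build_rigid_anatomy("liver")


class TestThorax:
    def test_bone_mask_autocorrelation_peaks_at_pitch(self):
        pitch = 25.0
        v = build_thoracic_anatomy(n_vertebrae=7, pitch_mm=pitch, seed=2,
                                   grid=GridSpec.cube(96, 2.5))
        bone = (v.voxels >= 0.9 * MU_BONE).sum(axis=(0, 1)).astype(float)
        bone -= bone.mean()
        ac = np.correlate(bone, bone, mode="full")[len(bone) - 1:]
        lag_vox = int(round(pitch / v.spacing_mm[2]))
        # secondary peak at one vertebra pitch
        window = ac[lag_vox - 2: lag_vox + 3]
        assert window.max() > 0.5 * ac[0]
        local = np.argmax(ac[3: 2 * lag_vox]) + 3
        assert abs(local - lag_vox) <= 2

    def test_single_vertebra_has_no_secondary_peak(self):
        v = build_thoracic_anatomy(n_vertebrae=1, pitch_mm=25.0, seed=2,
                                   grid=GridSpec.cube(96, 2.5))
        bone = (v.voxels >= 0.9 * MU_BONE).sum(axis=(0, 1)).astype(float)
        bone -= bone.mean()
        ac = np.correlate(bone, bone, mode="full")[len(bone) - 1:]
        assert ac[10] < 0.5 * ac[0]

    def test_requires_at_least_one_vertebra(self):
        with pytest.raises(ValueError):
            build_thoracic_anatomy(n_vertebrae=0)


class TestApplyRigid:
    def test_identity_returns_equal_volume(self, head_volume):
        out = apply_rigid(head_volume, RigidTransform())
        assert np.array_equal(out.voxels, head_volume.voxels)

    def test_one_voxel_translation_is_integer_shift(self, head_volume):
        d = float(head_volume.spacing_mm[0])
        out = apply_rigid(head_volume, RigidTransform(d, 0, 0))
        assert np.allclose(out.voxels[1:], head_volume.voxels[:-1], atol=1e-5)

    def test_round_trip_within_interpolation_tolerance(self, head_volume):
        from scipy import ndimage

        t = RigidTransform(3.1, -2.2, 1.4, 2.0, -1.5, 1.0)
        # smooth fixture: double trilinear resampling is near-exact on a
        # band-limited volume (sharp binary edges would dominate otherwise)
        smooth = Volume(
            ndimage.gaussian_filter(head_volume.voxels, 2.0),
            head_volume.spacing_mm, head_volume.origin_mm,
        )
        back = apply_rigid(apply_rigid(smooth, t, "cubic"), t.inverse(), "cubic")
        interior = tuple(slice(10, -10) for _ in range(3))
        err = np.abs(back.voxels[interior] - smooth.voxels[interior])
        assert err.max() < 0.01 * MU_BONE
        # raw sharp-edged volume: trilinear double resampling blurs binary
        # edges, but the average interior error stays a few percent of bone
        back_raw = apply_rigid(apply_rigid(head_volume, t), t.inverse())
        err_raw = np.abs(back_raw.voxels[interior]
                         - head_volume.voxels[interior])
        assert err_raw.mean() < 0.05 * MU_BONE


class TestDeformation:
    def test_zero_amplitude_is_identity(self, head_volume):
        params = DeformationParams(amplitude_mm=0.0, seed=3)
        out, u = apply_deformation(head_volume, params)
        assert np.array_equal(out.voxels, head_volume.voxels)
        assert np.all(u == 0)

    def test_displacement_bound_enforced(self, head_volume):
        params = DeformationParams(amplitude_mm=10.0, max_displacement_mm=0.5,
                                   seed=3)
        with pytest.raises(ValueError, match="exceeds bound"):
            apply_deformation(head_volume, params)

    def test_masked_centroid_moves_less_than_amplitude(self):
        grid = GridSpec.cube(64, 2.5)
        spec = PhantomSpec("ins", [
            Primitive("ellipsoid", (0, 0, 0), (60, 60, 60), MU_WATER),
            Primitive("ellipsoid", (10, 0, 0), (8, 8, 8), MU_BONE),
        ], grid)
        vol = spec.voxelize()
        a = 6.0
        params = DeformationParams(amplitude_mm=a, smoothness_mm=20.0,
                                   mask_center_mm=(10, 0, 0),
                                   mask_semi_axes_mm=(30, 30, 30), seed=4)
        out, _ = apply_deformation(vol, params)

        def centroid(v):
            m = v.voxels >= 0.9 * MU_BONE
            return v.index_to_world(np.argwhere(m)).mean(axis=0)

        shift = np.linalg.norm(centroid(out) - centroid(vol))
        assert 0 < shift <= a

    def test_total_attenuation_approximately_preserved(self, head_volume):
        params = DeformationParams(amplitude_mm=5.0, smoothness_mm=30.0,
                                   mask_semi_axes_mm=(60, 60, 60), seed=5)
        out, _ = apply_deformation(head_volume, params)
        assert out.voxels.sum() == pytest.approx(head_volume.voxels.sum(),
                                                 rel=0.05)


class TestVolumeContainer:
    def test_downsample_block_mean(self):
        v = Volume(np.arange(64, dtype=float).reshape(4, 4, 4),
                   np.ones(3), np.zeros(3))
        d = v.downsample(2)
        assert d.shape == (2, 2, 2)
        assert d.voxels[0, 0, 0] == pytest.approx(
            v.voxels[:2, :2, :2].mean())
        assert d.spacing_mm[0] == 2.0

    def test_world_index_round_trip(self, head_volume):
        pts = np.array([[0.0, 10.0, -20.0]])
        assert head_volume.index_to_world(
            head_volume.world_to_index(pts)) == pytest.approx(pts)
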