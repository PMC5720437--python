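import itertools

import numpy as np
import pytest

from sparsecbct.phantoms import (GridSpec, MU_BONE, MU_SOFT, PhantomSpec,
                                 Primitive, Volume, apply_rigid)
from sparsecbct.registration import (ChamferTarget, RegistrationOptions,
                                     chamfer_cost, extract_edges, ncc_cost,
                                     prepare_fixed, register)
from sparsecbct.transforms import RigidTransform


@pytest.fixture(scope="module")
def cube_volume():
    grid = GridSpec.cube(32, 2.0)
    spec = PhantomSpec("cube", [
        Primitive("box", (0, 0, 0), (16, 16, 16), MU_BONE)
    ], grid)
    return spec.voxelize()


@pytest.fixture(scope="module")
def blob_volume():
    """Asymmetric multi-body fixture whose pose is fully observable."""
    grid = GridSpec.cube(48, 2.0)
    spec = PhantomSpec("blobs", [
        Primitive("ellipsoid", (0, 0, 0), (38, 30, 26), MU_SOFT),
        Primitive("ellipsoid", (-10, 8, 4), (12, 9, 8), MU_BONE),
        Primitive("box", (14, -10, -6), (6, 8, 9), MU_BONE),
        Primitive("box", (4, 14, -12), (9, 4, 5), MU_BONE, rotation_deg=30),
        Primitive("ellipsoid", (-8, -14, 10), (6, 6, 9), MU_BONE),
        Primitive("ellipsoid", (12, 10, 12), (5, 7, 5), 0.0),  # air pocket
    ], grid)
    return spec.voxelize()


class TestExtractEdges:
    def test_constant_volume_raises(self):
        v = Volume(np.full((16, 16, 16), 0.02, np.float32), np.ones(3) * 2,
                   -np.ones(3) * 15)
        with pytest.raises(ValueError, match="no edge points"):
            extract_edges(v)

    def test_cube_edges_lie_on_faces(self, cube_volume):
        pts = extract_edges(cube_volume)
        # edge points concentrate on the faces of the 16 mm half-width cube
        dist_to_face = np.min(np.abs(np.abs(pts) - 16.0), axis=1)
        assert np.median(dist_to_face) < 2.0          # within one voxel
        assert np.percentile(dist_to_face, 95) < 3.2  # smoothing band
        # count comparable to the analytic face-voxel count (the smoothed
        # gradient keeps a band about 1.5 voxels thick around each face)
        face_voxels = 6 * 16 * 16
        assert 0.9 * face_voxels < len(pts) < 1.7 * face_voxels

    def test_threshold_monotonically_thins_edges(self, cube_volume):
        counts = [len(extract_edges(cube_volume, gradient_threshold=t))
                  for t in (0.003, 0.006, 0.012)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_refined_points_are_off_lattice(self, cube_volume):
        pts = extract_edges(cube_volume, refine=True)
        frac = np.abs(pts / cube_volume.spacing_mm
                      - np.round(pts / cube_volume.spacing_mm))
        assert frac.max() > 0.05


class TestChamferCost:
    def test_identity_cost_near_zero(self, blob_volume):
        opts = RegistrationOptions()
        # unrefined points coincide with the rasterized edge mask, so the
        # distance at identity is exactly zero up to interpolation
        pts = extract_edges(blob_volume, refine=False)
        target = ChamferTarget.from_edges(pts, blob_volume)
        c = chamfer_cost(target, pts, RigidTransform())
        assert c < 0.1 * float(np.min(blob_volume.spacing_mm))

    def test_far_translation_grows_linearly(self, blob_volume):
        opts = RegistrationOptions()
        target = ChamferTarget.from_volume(blob_volume, opts)
        pts = extract_edges(blob_volume)
        d1, d2 = 300.0, 600.0
        c1 = chamfer_cost(target, pts, RigidTransform(d1, 0, 0))
        c2 = chamfer_cost(target, pts, RigidTransform(d2, 0, 0))
        assert c1 == pytest.approx(d1, rel=0.2)
        assert (c2 - c1) == pytest.approx(d2 - d1, rel=0.05)

    def test_cost_is_lipschitz_in_translation(self, blob_volume):
        opts = RegistrationOptions()
        target = ChamferTarget.from_volume(blob_volume, opts)
        pts = extract_edges(blob_volume)
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(-5, 5, 3)
            delta = rng.uniform(-0.5, 0.5, 3)
            c1 = chamfer_cost(target, pts, RigidTransform(*p))
            c2 = chamfer_cost(target, pts, RigidTransform(*(p + delta)))
            assert abs(c2 - c1) <= np.linalg.norm(delta) + 1e-9

    def test_empty_moving_set_raises(self, blob_volume):
        target = ChamferTarget.from_volume(blob_volume, RegistrationOptions())
        with pytest.raises(ValueError):
            chamfer_cost(target, np.empty((0, 3)), RigidTransform())


class TestNccCost:
    def test_identity_is_perfect_correlation(self, blob_volume):
        c = ncc_cost(blob_volume, blob_volume, RigidTransform())
        assert c == pytest.approx(-1.0, abs=1e-6)

    def test_affine_rescaling_invariance(self, blob_volume):
        scaled = Volume(blob_volume.voxels * 3.7 + 0.01,
                        blob_volume.spacing_mm, blob_volume.origin_mm)
        c = ncc_cost(blob_volume, scaled, RigidTransform())
        assert c == pytest.approx(-1.0, abs=1e-6)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(3)
        sp, org = np.ones(3) * 2, -np.ones(3) * 47
        a = Volume(rng.normal(size=(48, 48, 48)).astype(np.float32), sp, org)
        b = Volume(rng.normal(size=(48, 48, 48)).astype(np.float32), sp, org)
        assert abs(ncc_cost(a, b, RigidTransform())) < 0.05

    def test_constant_overlap_raises(self, blob_volume):
        flat = Volume(np.full(blob_volume.shape, 0.01, np.float32),
                      blob_volume.spacing_mm, blob_volume.origin_mm)
        with pytest.raises(ValueError, match="constant"):
            ncc_cost(blob_volume, flat, RigidTransform())


class TestRegister:
    @pytest.mark.parametrize("mode", ["bone", "grey"])
    def test_recovers_small_transform(self, head_volume, mode):
        t_true = RigidTransform(3.0, -2.0, 1.5, 2.0, -1.0, 1.5)
        moving = apply_rigid(head_volume, t_true, "cubic")
        res = register(head_volume, moving, mode=mode)
        err = res.transform.params - t_true.inverse().params
        voxel = float(np.min(head_volume.spacing_mm))
        assert np.linalg.norm(err[:3]) < 0.2 * voxel
        assert np.abs(err[3:]).max() < 0.2

    def test_init_at_truth_is_fixed_point(self, head_volume):
        # integer-voxel shift: the resampled moving image is exact, so the
        # cost is already minimal at the true parameters
        d = float(head_volume.spacing_mm[0])
        t_true = RigidTransform(d, d, -d, 0, 0, 0)
        moving = apply_rigid(head_volume, t_true)
        res = register(head_volume, moving, mode="bone",
                       init=t_true.inverse())
        drift = res.transform.params - t_true.inverse().params
        assert np.abs(drift).max() < 0.1

    def test_idempotent_reregistration(self, blob_volume):
        t_true = RigidTransform(2.5, -1.5, 1.0, 1.0, 0.5, -1.0)
        moving = apply_rigid(blob_volume, t_true, "cubic")
        res1 = register(blob_volume, moving, mode="bone")
        res2 = register(blob_volume, moving, mode="bone", init=res1.transform)
        delta = res2.transform.params - res1.transform.params
        assert np.abs(delta[:3]).max() < 0.05
        assert np.abs(delta[3:]).max() < 0.05

    def test_bone_and_grey_agree_on_rigid_noiseless_fixture(self, head_volume):
        t_true = RigidTransform(2.0, -3.0, 1.0, 1.5, 1.0, -2.0)
        moving = apply_rigid(head_volume, t_true, "cubic")
        rb = register(head_volume, moving, mode="bone")
        rg = register(head_volume, moving, mode="grey")
        d = rb.transform.params - rg.transform.params
        assert np.abs(d[:3]).max() < 0.5
        assert np.abs(d[3:]).max() < 0.5

    def test_pose_offset_equals_inverse_condition(self, head_volume):
        t = RigidTransform(4.0, -2.0, 3.0, 2.0, 1.0, -1.5)
        res = register(head_volume, head_volume, mode="bone", pre_transform=t)
        err = res.transform.params - t.inverse().params
        assert np.abs(err[:3]).max() < 0.1
        assert np.abs(err[3:]).max() < 0.1

    def test_deterministic(self, blob_volume):
        t_true = RigidTransform(1.0, 2.0, -1.0, 0.5, -0.5, 1.0)
        moving = apply_rigid(blob_volume, t_true, "cubic")
        a = register(blob_volume, moving, mode="bone")
        b = register(blob_volume, moving, mode="bone")
        assert np.array_equal(a.transform.params, b.transform.params)
        assert a.n_evaluations == b.n_evaluations

    @pytest.mark.parametrize("mode", ["bone", "grey"])
    def test_matches_exhaustive_grid_search(self, blob_volume, mode):
        """Optimizer vs brute-force translation search on a 32-cube."""
        voxel = float(blob_volume.spacing_mm[0])
        t_true = RigidTransform(1.5 * voxel, -voxel, 0.5 * voxel, 0, 0, 0)
        moving = apply_rigid(blob_volume, t_true)
        opts = RegistrationOptions()
        if mode == "bone":
            target = ChamferTarget.from_volume(blob_volume, opts)
            pts = extract_edges(moving)

            def cost(tx, ty, tz):
                return chamfer_cost(target, pts,
                                    RigidTransform(tx, ty, tz))
        else:
            def cost(tx, ty, tz):
                return ncc_cost(blob_volume, moving,
                                RigidTransform(tx, ty, tz))

        steps = np.arange(-3, 4) * voxel
        grid_costs = {
            t: cost(*t) for t in itertools.product(steps, steps, steps)
        }
        t_grid = np.array(min(grid_costs, key=grid_costs.get))
        res = register(blob_volume, moving, mode=mode)
        assert np.abs(res.transform.params[:3] - t_grid).max() <= voxel
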