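import numpy as np
import pytest

import vesselmarks as vm
from vesselmarks.sphere_growing import DivergenceReason, _shell_samples

from conftest import edt_oracle, make_ball_patch


class TestOpposingForce:
    def test_constant_patch_gives_zero_force(self):
        patch = vm.Volume(np.full((9, 9, 9), 100.0))
        u = vm.opposing_force_field(patch).vectors
        np.testing.assert_allclose(u, 0.0, atol=1e-12)

    def test_force_magnitude_bounded_by_one(self, rng):
        patch = vm.Volume(rng.normal(0, 300, size=(12, 12, 12)))
        u = vm.opposing_force_field(patch).vectors
        assert np.linalg.norm(u, axis=-1).max() <= 1.0 + 1e-9

    def test_border_force_points_into_bright_ball(self):
        patch, mask = make_ball_patch(6.0, (15, 15, 15), n=31)
        u = vm.opposing_force_field(patch).vectors
        # independently locate border voxels and the inward direction
        idx = np.indices(patch.shape).reshape(3, -1).T.astype(float)
        dist = np.linalg.norm(idx - 15.0, axis=1).reshape(patch.shape)
        border = np.abs(dist - 6.0) < 1.0
        inward = (15.0 - idx).reshape(patch.shape + (3,))
        inward /= np.linalg.norm(inward, axis=-1, keepdims=True) + 1e-12
        dots = np.einsum("...i,...i->...", u, inward)[border]
        mags = np.linalg.norm(u, axis=-1)[border]
        # deep inside the bright ball the force vanishes; wherever it acts on
        # the border band it must point toward the ball center
        assert np.all(dots > -1e-9)
        assert np.mean(dots[mags > 1e-3] > 0.5) > 0.95

    def test_anisotropic_patch_rejected(self):
        patch = vm.Volume(np.zeros((5, 5, 5)), spacing=np.array([1.0, 1.0, 2.0]))
        with pytest.raises(ValueError):
            vm.opposing_force_field(patch)


class TestZeroForceClosedForm:
    def test_radius_recurrence_and_stationary_center(self):
        patch = vm.Volume(np.full((31, 31, 31), 50.0))
        cfg = vm.GrowthConfig(n_iter=30)
        traj = vm.grow_sphere(patch, [15.0, 15.0, 15.0], cfg)
        # free expansion with nothing to converge to is reported as such
        assert traj.divergence_reason == DivergenceReason.NO_CONVERGENCE
        for st in traj.states:
            assert abs(st.radius - (cfg.r0 + st.iteration * cfg.f_int)) < 1e-9
            assert np.array_equal(st.center, np.array([15.0, 15.0, 15.0]))
        radii = [st.radius for st in traj.states]
        assert all(b > a for a, b in zip(radii, radii[1:]))  # strictly increasing


class TestBallOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_maximal_inscribed_sphere(self, seed):
        rng = np.random.default_rng(seed)
        radius = rng.uniform(3, 8)
        center = 20.0 + rng.uniform(-0.5, 0.5, 3)
        patch, mask = make_ball_patch(radius, center, n=41)
        seed_pt = center + rng.uniform(-1, 1, 3) * 2 / np.sqrt(3)
        traj = vm.grow_sphere(patch, seed_pt, vm.GrowthConfig(n_iter=200))
        oracle_center, oracle_radius = edt_oracle(mask)
        assert not traj.diverged
        assert np.linalg.norm(traj.final.center - oracle_center) <= 0.5
        assert abs(traj.final.radius - oracle_radius) <= 1.0

    def test_junction_center_reaches_distance_transform_maxima(self, junction_case):
        vol, lm, spec = junction_case
        patch = vm.hu_window(vol)
        seed = patch.world_to_voxel(lm.position) + np.array([1.2, -0.9, 0.8])
        traj = vm.grow_sphere(patch, seed, vm.GrowthConfig(n_iter=60))
        # oracle: set of EDT maxima of the vessel mask near the junction
        # (constant-radius tubes give a flat EDT ridge, so the maximum is a
        # plateau, not a single point)
        from scipy import ndimage
        mask = vol.voxels > 80.0  # half intensity between -80 and 240
        edt = ndimage.distance_transform_edt(mask)
        j = np.round(vol.world_to_voxel(lm.position)).astype(int)
        lo = np.maximum(j - 8, 0); hi = j + 9
        sub = edt[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        plateau = lo + np.argwhere(sub >= sub.max() - 0.5)
        gap = np.linalg.norm(plateau - traj.final.center, axis=1).min()
        assert not traj.diverged
        assert gap <= 1.0


class TestDivergence:
    def test_stable_run_not_diverged(self, junction_case):
        vol, lm, _ = junction_case
        patch = vm.hu_window(vol)
        traj = vm.grow_sphere(patch, patch.world_to_voxel(lm.position),
                              vm.GrowthConfig(n_iter=60))
        assert vm.detect_divergence(traj, patch) == (False, DivergenceReason.NONE)

    def test_radius_cap_hit_at_closed_form_iteration(self):
        patch = vm.Volume(np.full((61, 61, 61), 50.0))
        cfg = vm.GrowthConfig(n_iter=100, radius_cap_voxels=4.9)
        traj = vm.grow_sphere(patch, [30.0, 30.0, 30.0], cfg)
        assert traj.diverged and traj.divergence_reason == DivergenceReason.RADIUS_CAP
        # first n with r0 + n*f_int > cap
        n_expected = int(np.floor((cfg.radius_cap_voxels - cfg.r0) / cfg.f_int)) + 1
        assert traj.final.iteration == n_expected
        assert vm.detect_divergence(traj, patch, cfg)[0]

    def test_forced_drift_leaves_patch(self):
        # linear ramp: u points along +x everywhere, pushing the center out
        n = 13
        x = np.arange(n, dtype=float)
        vox = np.broadcast_to(-160 + 200 * x[:, None, None] / n, (n, n, n)).copy()
        patch = vm.Volume(vox)
        cfg = vm.GrowthConfig(n_iter=400, drift_cap_voxels=1e6, radius_cap_voxels=1e6,
                              f_int=1e-3)
        traj = vm.grow_sphere(patch, [n - 2.0, 6.0, 6.0], cfg)
        assert traj.diverged
        assert traj.divergence_reason == DivergenceReason.LEFT_PATCH

    def test_center_drift_cap(self):
        n = 31
        x = np.arange(n, dtype=float)
        vox = np.broadcast_to(-160 + 200 * x[:, None, None] / n, (n, n, n)).copy()
        patch = vm.Volume(vox)
        cfg = vm.GrowthConfig(n_iter=400, drift_cap_voxels=3.0, radius_cap_voxels=1e6,
                              f_int=1e-3)
        traj = vm.grow_sphere(patch, [5.0, 15.0, 15.0], cfg)
        assert traj.diverged and traj.divergence_reason == DivergenceReason.CENTER_DRIFT


class TestInvariances:
    def test_determinism_bit_identical(self, junction_case):
        vol, lm, _ = junction_case
        patch = vm.hu_window(vol)
        seed = patch.world_to_voxel(lm.position)
        t1 = vm.grow_sphere(patch, seed)
        t2 = vm.grow_sphere(patch, seed)
        for a, b in zip(t1.states, t2.states):
            assert np.array_equal(a.center, b.center) and a.radius == b.radius

    def test_axis_permutation_consistency(self, junction_case):
        vol, lm, _ = junction_case
        patch = vm.hu_window(vol)
        seed = patch.world_to_voxel(lm.position) + np.array([0.7, -0.4, 0.2])
        t1 = vm.grow_sphere(patch, seed, vm.GrowthConfig(n_iter=60))
        swapped = vm.Volume(np.transpose(patch.voxels, (1, 0, 2)))
        t2 = vm.grow_sphere(swapped, seed[[1, 0, 2]], vm.GrowthConfig(n_iter=60))
        np.testing.assert_allclose(
            t2.final.center[[1, 0, 2]], t1.final.center, atol=0.25
        )

    def test_shell_sample_count_scales_with_radius(self):
        assert len(_shell_samples(np.zeros(3), 0.5, 1.5)) >= 3 * 64
        assert len(_shell_samples(np.zeros(3), 6.0, 1.5)) >= 3 * int(4 * np.pi * 36)


class TestRefineLandmark:
    def test_ideal_junction_refined_on_image(self, junction_case):
        vol, lm, _ = junction_case
        start = lm.moved_to(lm.position + np.array([1.5, -1.0, 0.8]),
                            bifurcation_type=vm.BifurcationType.TYPE1)
        cfg = vm.GrowthConfig(patch_size_mm=50.0, n_iter=60)
        refined, traj = vm.refine_landmark(vol, start, cfg)
        assert refined.substrate == vm.Substrate.IMAGE
        assert not refined.flagged
        # must land in the widest junction region (distance-transform maxima)
        from scipy import ndimage
        mask = vol.voxels > 80.0
        edt = ndimage.distance_transform_edt(mask)
        j = np.round(vol.world_to_voxel(lm.position)).astype(int)
        sub = edt[j[0]-8:j[0]+9, j[1]-8:j[1]+9, j[2]-8:j[2]+9]
        plateau_mm = vol.voxel_to_world(j - 8 + np.argwhere(sub >= sub.max() - 0.5))
        gap_mm = np.linalg.norm(plateau_mm - refined.position, axis=1).min()
        assert gap_mm <= 1.0  # one resampled voxel plus grid slack

    def test_type2_landmark_rejected(self, junction_case):
        vol, lm, _ = junction_case
        t2 = lm.moved_to(lm.position, bifurcation_type=vm.BifurcationType.TYPE2)
        with pytest.raises(ValueError):
            vm.refine_landmark(vol, t2)

    def test_vessel_free_patch_flags_landmark(self):
        vol = vm.Volume(np.full((41, 41, 41), -80.0), spacing=np.full(3, 1.5))
        lm = vm.Landmark(vol.voxel_to_world([20, 20, 20]), "L0",
                         bifurcation_type=vm.BifurcationType.TYPE1)
        cfg = vm.GrowthConfig(patch_size_mm=40.0)
        refined, traj = vm.refine_landmark(vol, lm, cfg)
        assert refined.flagged
        assert refined.substrate == vm.Substrate.NONE
        np.testing.assert_array_equal(refined.position, lm.position)

    def test_fallback_to_manual_mask(self, junction_case):
        vol, lm, _ = junction_case
        # constant image: raw substrate and vesselness both fail; a manual
        # mask of the vessel tree lets the run converge
        flat = vol.with_voxels(np.full(vol.shape, -80.0))
        mask = vol.with_voxels((vol.voxels > 80.0).astype(float))
        start = lm.moved_to(lm.position, bifurcation_type=vm.BifurcationType.TYPE1)
        cfg = vm.GrowthConfig(patch_size_mm=50.0, n_iter=60)
        refined, traj = vm.refine_landmark(flat, start, cfg, manual_mask=mask)
        assert refined.substrate == vm.Substrate.MANUAL_MASK
        assert np.linalg.norm(refined.position - lm.position) < 3.0
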