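import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dynevo.essential_dynamics import (ConvergenceError, ModeSet, WindowSpec,
                                       align_and_center, check_convergence,
                                       covariance, eigenmodes,
                                       fluctuation_profile,
                                       sliding_window_pca, trajectory_modes)
from dynevo.structure_io import Trajectory
from dynevo.synthetic_data import build_enm, enm_covariance, make_toy_chain, \
    sample_ensemble

from oracles import naive_align, naive_covariance, power_iteration_eigh


def _traj(frames):
    n = frames.shape[1]
    return Trajectory(frames, np.arange(1, n + 1), ["ALA"] * n)


class TestAlignAndCenter:
    def test_rigid_motions_removed(self, rng):
        base = rng.normal(scale=4.0, size=(8, 3))
        rots = Rotation.random(12, random_state=1).as_matrix()
        trans = rng.uniform(-10, 10, size=(12, 3))
        frames = np.einsum("tij,nj->tni", rots, base) + trans[:, None, :]
        aligned = align_and_center(_traj(frames)).frames
        spread = aligned - aligned.mean(axis=0)
        assert np.abs(spread).max() < 1e-8

    def test_idempotent_on_aligned_input(self, small_trajectory):
        once = align_and_center(small_trajectory)
        twice = align_and_center(once)
        np.testing.assert_allclose(twice.frames, once.frames, atol=1e-10)

    def test_matches_unbatched_reference_implementation(self, small_trajectory):
        ours = align_and_center(small_trajectory).frames
        ref = naive_align(small_trajectory.frames)
        np.testing.assert_allclose(ours, ref, atol=1e-8)


class TestCovariance:
    def test_identical_frames_give_zero(self):
        frames = np.tile(np.arange(12.0).reshape(1, 4, 3), (5, 1, 1))
        assert np.abs(covariance(frames)).max() == 0.0

    def test_one_dimensional_hand_case(self):
        # one site moving 0 -> 2 along x: population variance is 1.0
        frames = np.zeros((2, 1, 3))
        frames[1, 0, 0] = 2.0
        c = covariance(frames)
        assert c[0, 0] == pytest.approx(1.0, abs=1e-15)
        assert np.abs(c).sum() == pytest.approx(1.0, abs=1e-15)

    def test_matches_double_loop_oracle(self, rng):
        frames = rng.normal(size=(20, 5, 3))
        np.testing.assert_allclose(covariance(frames),
                                   naive_covariance(frames), atol=1e-12)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            covariance(np.zeros((1, 4, 3)))


class TestEigenmodes:
    def test_diagonal_case(self):
        c = np.diag([4.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        ms = eigenmodes(c)
        np.testing.assert_allclose(ms.eigenvalues[:2], [4.0, 1.0])
        np.testing.assert_allclose(np.abs(ms.eigenvectors[0, 0]), 1.0)
        assert ms.eigenvectors[0, 0] > 0  # sign convention

    def test_trace_identity_and_orthonormality(self, rng):
        a = rng.normal(size=(18, 18))
        c = a @ a.T
        ms = eigenmodes(c, n_modes=18)
        assert np.sum(ms.eigenvalues) == pytest.approx(np.trace(c), rel=1e-10)
        gram = ms.eigenvectors.T @ ms.eigenvectors
        np.testing.assert_allclose(gram, np.eye(18), atol=1e-8)

    def test_matches_power_iteration_oracle(self):
        r = np.random.default_rng(5)
        a = r.normal(size=(30, 30))
        c = a @ a.T
        ms = eigenmodes(c, n_modes=5)
        vals, vecs = power_iteration_eigh(c, 5)
        np.testing.assert_allclose(ms.eigenvalues[:5], vals, rtol=1e-6)
        for k in range(5):
            cos = abs(ms.eigenvectors[:, k] @ vecs[:, k])
            assert cos > 1 - 1e-6

    def test_asymmetric_matrix_rejected(self, rng):
        c = rng.normal(size=(6, 6))
        with pytest.raises(ValueError):
            eigenmodes(c)

    def test_mode_cap_enforced(self, rng):
        a = rng.normal(size=(45, 45))
        ms = eigenmodes(a @ a.T, n_modes=45)
        assert ms.n_modes == 30

    def test_json_round_trip(self, small_trajectory):
        ms = trajectory_modes(small_trajectory)
        back = ModeSet.from_json(ms.to_json())
        np.testing.assert_allclose(back.eigenvalues, ms.eigenvalues)
        np.testing.assert_allclose(back.eigenvectors, ms.eigenvectors)


class TestFluctuationProfile:
    def test_localized_mode(self):
        vec = np.zeros(18)
        vec[12] = 1.0  # x of site 5 (0-based 4)
        ms = ModeSet(np.array([2.0]), vec[:, None], np.zeros((6, 3)))
        prof = fluctuation_profile(ms, 1)
        assert prof.values[4] == pytest.approx(2.0)
        assert np.sum(prof.values) == pytest.approx(2.0)

    def test_spread_mode_normalization(self):
        vec = np.zeros(12)
        vec[0::3] = 0.5  # equal x-weight on 4 sites
        ms = ModeSet(np.array([1.0]), vec[:, None], np.zeros((4, 3)))
        prof = fluctuation_profile(ms, 1)
        np.testing.assert_allclose(prof.values, 0.25)

    def test_profile_sums_to_eigenvalue(self, small_trajectory):
        ms = trajectory_modes(small_trajectory)
        for rank in range(1, ms.n_modes + 1):
            prof = fluctuation_profile(ms, rank)
            assert np.all(prof.values >= 0)
            assert np.sum(prof.values) == pytest.approx(
                ms.eigenvalues[rank - 1], abs=1e-10)

    def test_rank_out_of_range(self, small_trajectory):
        ms = trajectory_modes(small_trajectory)
        with pytest.raises(ValueError):
            fluctuation_profile(ms, ms.n_modes + 1)


class TestSlidingWindow:
    def test_window_arithmetic(self, rng):
        frames = rng.normal(size=(20, 4, 3)) + rng.normal(scale=5, size=(1, 4, 3))
        sets = sliding_window_pca(_traj(frames), WindowSpec(10, 5))
        assert [ms.window_id for ms in sets] == [0, 1, 2]

    def test_full_length_window(self, rng):
        frames = rng.normal(size=(10, 4, 3)) + rng.normal(scale=5, size=(1, 4, 3))
        assert len(sliding_window_pca(_traj(frames), WindowSpec(10, 10))) == 1

    def test_window_longer_than_trajectory_rejected(self, small_trajectory):
        with pytest.raises(ValueError):
            sliding_window_pca(small_trajectory, WindowSpec(100, 50))

    def test_stationary_windows_share_top_eigenvalue(self):
        chain = make_toy_chain(10, "helix")
        cov = enm_covariance(build_enm(chain))
        lam_true = eigenmodes(cov).eigenvalues[0]
        traj = sample_ensemble(cov, chain, 3000, seed=8)
        sets = sliding_window_pca(traj, WindowSpec(1000, 1000))
        for ms in sets:
            assert ms.eigenvalues[0] == pytest.approx(lam_true, rel=0.2)


def _modeset_from_profile(profile, window_id):
    """ModeSet whose slowest-mode fluctuation profile equals ``profile``."""
    profile = np.asarray(profile, dtype=float)
    lam = profile.sum()
    v = np.zeros(3 * len(profile))
    v[0::3] = np.sqrt(profile / lam)
    return ModeSet(np.array([lam]), v[:, None],
                   np.zeros((len(profile), 3)), window_id)


class TestCheckConvergence:
    def test_identical_profiles_converge(self):
        sets = [_modeset_from_profile([1.0, 2.0, 3.0, 4.0], i) for i in range(5)]
        res = check_convergence(sets, WindowSpec(10, 5, 4))
        np.testing.assert_allclose(res.pearson_by_pair, 1.0)
        assert res.converged and res.converged_at == 4

    def test_anticorrelated_profiles_do_not_converge(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a.max() + a.min() - a  # Pearson -1 with a
        sets = [_modeset_from_profile(a if i % 2 == 0 else b, i) for i in range(4)]
        res = check_convergence(sets, WindowSpec(10, 5, 2))
        np.testing.assert_allclose(res.pearson_by_pair, -1.0, atol=1e-12)
        assert not res.converged and res.converged_at is None

    def test_converged_at_follows_hand_walk_of_rule(self):
        # profiles: two regimes; comparisons fail across the switch only
        p1, p2 = [1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]
        seq = [p1, p1, p1, p2, p2, p2, p2, p2]
        sets = [_modeset_from_profile(p, i) for i, p in enumerate(seq)]
        spec = WindowSpec(10, 5, 3)
        res = check_convergence(sets, spec)
        # comparisons: pass pass FAIL pass pass pass pass -> first run of 3
        # passes ends at comparison index 6 -> window 7 (hand walk)
        passing = res.pearson_by_pair > res.threshold
        assert list(passing) == [True, True, False, True, True, True, True]
        assert res.converged and res.converged_at == 6

    def test_constant_profile_is_an_error(self):
        sets = [_modeset_from_profile([1.0, 1.0, 1.0, 1.0], i) for i in range(3)]
        with pytest.raises(ConvergenceError, match="constant fluctuation profile"):
            check_convergence(sets, WindowSpec(10, 5, 2))

    def test_too_few_windows_rejected(self):
        sets = [_modeset_from_profile([1.0, 2.0, 3.0], 0)]
        with pytest.raises(ValueError):
            check_convergence(sets, WindowSpec(10, 5))


class TestWindowSpec:
    @pytest.mark.parametrize("length,stride", [(10, 0), (10, 11), (0, 1)])
    def test_invalid_layout_rejected(self, length, stride):
        with pytest.raises(ValueError):
            WindowSpec(length, stride)
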