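import numpy as np
import pytest
from scipy.spatial import procrustes as scipy_procrustes

import popdyn as P
from popdyn.binning import DEFAULT_GRID


def _hold_then_move(path_fn, m=3):
    """Trajectory at the origin before onset, following path_fn(s) for
    s in [0, 1] over 0-500 ms, then holding the endpoint."""
    T = DEFAULT_GRID.n_bins
    t = DEFAULT_GRID.centers_ms
    traj = np.zeros((m, T))
    move = (t >= 0) & (t < 500)
    s = (t[move] - t[move][0]) / (t[move][-1] - t[move][0])
    seg = np.stack([path_fn(si) for si in s], axis=1)
    traj[:, move] = seg
    traj[:, t >= 500] = seg[:, [-1]]
    return traj


class TestPathMetrics:
    def test_straight_path_ratio_one(self):
        end = np.array([1.0, 2.0, -1.0])
        traj = _hold_then_move(lambda s: s * end)
        pm = P.path_metrics(traj, "onset")
        assert pm.distance_ratio == pytest.approx(1.0, abs=1e-9)
        assert pm.direct_distance == pytest.approx(np.linalg.norm(end), rel=0.05)

    def test_semicircle_ratio_pi_over_two(self):
        def arc(s):
            ang = np.pi * s
            return np.array([0.5 - 0.5 * np.cos(ang), 0.5 * np.sin(ang), 0.0])

        traj = _hold_then_move(arc)
        pm = P.path_metrics(traj, "onset")
        assert pm.distance_ratio == pytest.approx(np.pi / 2, rel=0.01)

    def test_ratio_at_least_one_on_random_smooth_paths(self, rng):
        for _ in range(10):
            ctrl = rng.normal(size=(3, 6))
            traj = _hold_then_move(
                lambda s: sum(c * s**k for k, c in enumerate(ctrl.T))
            )
            pm = P.path_metrics(traj, "onset")
            assert pm.distance_ratio >= 1.0 - 1e-9

    def test_spiral_less_direct_than_relaxation(self):
        # generative oracle: the oscillatory (stationary-regime) latent
        # takes a longer path than the matched direct relaxation
        cfg = P.SynthConfig(seed=0)
        z_osc = P.generate_latents(cfg, "stationary", 320.0)
        z_dir = P.generate_latents(cfg, "locomotion", 320.0)
        r_osc = P.path_metrics(z_osc, "onset").distance_ratio
        r_dir = P.path_metrics(z_dir, "onset").distance_ratio
        assert r_osc > r_dir
        assert r_dir < 1.5

    def test_unknown_epoch(self):
        with pytest.raises(ValueError):
            P.path_metrics(np.zeros((2, 200)), "middle")


class TestKinematics:
    def test_uniform_motion_constant_speed_zero_accel(self):
        t = np.arange(200) * 0.01
        traj = np.stack([2.0 * t, -1.0 * t])
        k = P.kinematics(traj)
        v = np.linalg.norm([2.0, -1.0]) / 2  # per-factor normalisation m=2
        np.testing.assert_allclose(k.speed, v, atol=1e-9)
        np.testing.assert_allclose(k.acceleration, 0.0, atol=1e-6)

    def test_circular_motion_constant_tangential_speed(self):
        t = np.arange(200) * 0.01
        r, w = 2.0, 2 * np.pi * 1.0
        traj = np.stack([r * np.cos(w * t), r * np.sin(w * t)])
        k = P.kinematics(traj)
        assert k.speed.std() / k.speed.mean() < 0.01
        assert np.abs(k.acceleration).max() < 0.1 * k.speed.mean() / 0.01

    def test_oscillatory_trajectory_has_less_low_band_power(self):
        # a 4 Hz spiral rectifies into speed fluctuations at and above
        # the oscillation frequency, pulling acceleration power out of
        # the 0-6 Hz band relative to a drift-matched smooth trajectory
        t = np.arange(200) * 0.01
        drift = np.stack([1.5 * (1 - np.exp(-t / 0.3)), np.zeros_like(t),
                          np.zeros_like(t)])
        w = 2 * np.pi * 4.0
        env = np.exp(-2.0 * t)
        osc = drift + np.stack(
            [np.zeros_like(t), env * np.sin(w * t), env * (np.cos(w * t) - 1)]
        )
        assert P.kinematics(osc).low_band_fraction < \
            P.kinematics(drift).low_band_fraction

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            P.kinematics(np.zeros((0, 100)))


class TestAngleOfApproach:
    def test_straight_approach_zero_deviation(self):
        traj = _hold_then_move(lambda s: s * np.array([1.0, 0.0, 0.0]))
        a = P.angle_of_approach(traj, "onset")
        sel = (DEFAULT_GRID.centers_ms > 0) & (DEFAULT_GRID.centers_ms < 450)
        assert np.nanmax(a.theta_deg[sel]) < 1e-6
        assert a.cumulative_deviation_deg == pytest.approx(0.0, abs=1e-6)

    def test_perpendicular_point_is_ninety_degrees(self):
        # trajectory point displaced perpendicular to the reference vector
        traj = _hold_then_move(lambda s: s * np.array([1.0, 0.0, 0.0]))
        i = DEFAULT_GRID.bin_of(250.0)
        traj2 = traj.copy()
        traj2[:, i] = traj2[:, i] + np.array([0.0, 3.0, 0.0]) \
            - (traj2[:, i] - np.array([1.0, 0.0, 0.0]))  # b exactly _|_ a
        a = P.angle_of_approach(traj2, "onset")
        assert a.theta_deg[i] == pytest.approx(90.0, abs=1e-6)

    def test_matches_bruteforce_arccos(self, rng):
        traj = rng.normal(size=(3, 200))
        a = P.angle_of_approach(traj, "onset")
        x_init = traj[:, DEFAULT_GRID.slice_ms(-200, 0)].mean(axis=1)
        x_fin = traj[:, DEFAULT_GRID.slice_ms(500, 1000)].mean(axis=1)
        ref = x_fin - x_init
        for i in [30, 60, 90]:
            b = x_fin - traj[:, i]
            expect = np.degrees(
                np.arccos(ref @ b / (np.linalg.norm(ref) * np.linalg.norm(b)))
            )
            assert a.theta_deg[i] == pytest.approx(expect, abs=1e-9)

    def test_spiral_deviates_more_than_relaxation(self):
        cfg = P.SynthConfig(seed=0)
        z_osc = P.generate_latents(cfg, "stationary", 320.0)
        z_dir = P.generate_latents(cfg, "locomotion", 320.0)
        assert P.angle_of_approach(z_osc, "onset").cumulative_deviation_deg > \
            P.angle_of_approach(z_dir, "onset").cumulative_deviation_deg


def _brute_force_tangling(traj, eps, half):
    x = traj[:, 1:]
    v = np.diff(traj, axis=1) / 0.01
    T = x.shape[1]
    Q = np.full(T, np.nan)
    for t in range(T):
        vals = []
        for tp in range(T):
            if tp == t or abs(tp - t) > half:
                continue
            num = np.sum((v[:, t] - v[:, tp]) ** 2)
            den = np.sum((x[:, t] - x[:, tp]) ** 2) + eps
            vals.append(num / den)
        if len(vals) >= 2:
            Q[t] = np.percentile(vals, 90.0)
    return Q


class TestTangling:
    def test_straight_line_zero(self):
        t = np.arange(200) * 0.01
        traj = np.stack([t, 2 * t])
        _, Q = P.tangling(traj)
        np.testing.assert_allclose(Q[np.isfinite(Q)], 0.0, atol=1e-12)

    def test_hairpin_matches_bruteforce_all_pairs(self):
        # 20-point hand-built curve that retraces itself
        fwd = np.linspace(0, 1, 10)
        path = np.concatenate([fwd, fwd[::-1][1:], [0.1]])
        traj = np.stack([path, 0.05 * np.arange(len(path))])
        eps = 0.1
        _, Q = P.tangling(traj, eps=eps, window_ms=2 * len(path) * 10)
        expect = _brute_force_tangling(traj, eps, half=len(path))
        np.testing.assert_allclose(Q, expect, rtol=1e-9)
        # with a local window the turn dwarfs the straight limbs
        _, Qloc = P.tangling(traj, eps=eps, window_ms=60.0)
        turn = len(fwd) - 1
        assert Qloc[turn] > 10 * Qloc[3]

    def test_epsilon_monotonicity(self, rng):
        traj = rng.normal(size=(2, 60))
        _, q1 = P.tangling(traj, eps=0.1)
        _, q2 = P.tangling(traj, eps=10.0)
        ok = np.isfinite(q1)
        assert np.all(q2[ok] <= q1[ok] + 1e-12)

    def test_translation_and_scale_invariance_with_adaptive_eps(self, rng):
        traj = rng.normal(size=(3, 80))
        _, q = P.tangling(traj)
        _, q_shift = P.tangling(traj + 5.0)
        _, q_scaled = P.tangling(3.0 * traj)
        np.testing.assert_allclose(q, q_shift, rtol=1e-9)
        np.testing.assert_allclose(q, q_scaled, rtol=1e-9)

    def test_shared_epsilon_pools_scale(self):
        a = np.zeros((2, 50))
        b = np.stack([np.linspace(0, 10, 50), np.zeros(50)])
        eps = P.tangling_epsilon([a, b])
        assert eps > P.tangling_epsilon([a])


class TestProcrustes:
    def test_similarity_transform_scores_one(self, rng):
        X = rng.normal(size=(30, 3))
        ang = 0.7
        R = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0],
             [0, 0, 1.0]]
        )
        Y = 2.5 * X @ R + np.array([1.0, -2.0, 0.5])
        assert P.procrustes_similarity(X, Y) == pytest.approx(1.0, abs=1e-9)

    def test_reflection_allowed(self, rng):
        X = rng.normal(size=(25, 2))
        Y = X.copy()
        Y[:, 0] *= -1
        assert P.procrustes_similarity(X, Y) == pytest.approx(1.0, abs=1e-9)

    def test_line_vs_circle_matches_scipy(self):
        t = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        X = np.stack([np.linspace(0, 1, 40), np.zeros(40)], axis=1)
        Y = np.stack([np.cos(t), np.sin(t)], axis=1)
        ours = P.procrustes_similarity(X, Y)
        _, _, disparity = scipy_procrustes(X, Y)
        assert ours < 1.0
        assert ours == pytest.approx(1.0 - disparity, abs=1e-9)

    def test_invariant_under_similarity_transform_of_source(self, rng):
        X = rng.normal(size=(20, 3))
        Y = rng.normal(size=(20, 3))
        base = P.procrustes_similarity(X, Y)
        Y2 = 0.3 * Y + 7.0
        assert P.procrustes_similarity(X, Y2) == pytest.approx(base, abs=1e-9)

    def test_degenerate_target_is_missing(self):
        X = np.zeros((10, 2))
        Y = np.random.default_rng(0).normal(size=(10, 2))
        assert np.isnan(P.procrustes_similarity(X, Y))


class TestInterTrajectoryDistance:
    def test_identical_trajectories_give_zero(self, rng):
        tj = rng.normal(size=(3, 50))
        d = P.inter_trajectory_distance({v: tj for v in range(6)})
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_equidistant_offsets_give_constant(self):
        base = np.zeros((2, 30))
        trajs = {
            0: base,
            1: base + np.array([[3.0], [0.0]]),
            2: base + np.array([[1.5], [1.5 * np.sqrt(3)]]),
        }
        d = P.inter_trajectory_distance(trajs)
        np.testing.assert_allclose(d, 3.0, atol=1e-9)

    def test_missing_conditions_rejected(self):
        with pytest.raises(ValueError):
            P.inter_trajectory_distance({0: np.zeros((2, 10))})
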