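"""Fast-modality kinetics: MSD, per-track D, 3-state fit, angles, confinement."""

import numpy as np
import pytest
from scipy import stats

from bindscape.fastkinetics import (
    D_BOUNDS,
    anisotropy,
    cell_features,
    confinement_radius,
    features_pca,
    fit_msd_powerlaw,
    fit_three_state,
    jump_angles,
    msd_curve,
    per_track_diffusion,
    radius_of_gyration,
    split_mobile_immobile,
)
from bindscape.simulate import SmtSimConfig, simulate_trajectories
from bindscape.trajectories import Trajectory


def brownian_track(rng, d, n, dt=0.02, sigma=0.0, track_id=0):
    steps = rng.normal(0, np.sqrt(2 * d * dt), size=(n - 1, 2))
    pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    obs = pos + rng.normal(0, sigma, size=pos.shape)
    return Trajectory(track_id, np.arange(n), obs[:, 0], obs[:, 1], dt)


class TestMsd:
    def test_immobile_with_noise_plateaus_at_4_sigma_sq(self):
        rng = np.random.default_rng(1)
        sigma = 0.035
        traj = brownian_track(rng, 0.0, 3000, sigma=sigma)
        curve = msd_curve(traj)
        plateau = 4 * sigma**2
        assert np.median(curve[:, 1]) == pytest.approx(plateau, rel=0.10)

    def test_linear_motion_quadratic_msd(self):
        v = 0.5  # um/s
        dt = 0.02
        n = 50
        t = np.arange(n)
        traj = Trajectory(0, t, v * t * dt, np.zeros(n), dt)
        curve = msd_curve(traj)
        for lag_s, msd in curve:
            assert msd == pytest.approx((v * lag_s) ** 2, rel=1e-9)

    def test_brownian_msd_matches_generative_model(self):
        rng = np.random.default_rng(2)
        d, sigma, dt = 0.5, 0.02, 0.02
        curves = [msd_curve(brownian_track(rng, d, 60, sigma=sigma))[:5, 1]
                  for _ in range(400)]
        mean_curve = np.mean(curves, axis=0)
        lags = (np.arange(5) + 1) * dt
        expected = 4 * d * lags + 4 * sigma**2
        assert np.allclose(mean_curve, expected, rtol=0.1)


class TestMsdPowerlaw:
    def test_exact_linear_curve_inverted(self):
        t = np.arange(1, 20) * 0.02
        curve = np.column_stack([t, 4 * 0.2 * t + 0.0])
        fit = fit_msd_powerlaw(curve)
        assert fit.d_app == pytest.approx(0.2, abs=1e-4)
        assert fit.alpha == pytest.approx(1.0, abs=1e-3)

    def test_exact_subdiffusive_curve_inverted(self):
        t = np.arange(1, 20) * 0.02
        curve = np.column_stack([t, 4 * 0.1 * t**0.5])
        fit = fit_msd_powerlaw(curve)
        assert fit.alpha == pytest.approx(0.5, abs=1e-3)

    def test_brownian_alpha_near_one(self):
        rng = np.random.default_rng(3)
        alphas = []
        for i in range(500):
            traj = brownian_track(rng, 0.3, 50, sigma=0.0, track_id=i)
            alphas.append(fit_msd_powerlaw(msd_curve(traj)).alpha)
        assert 0.9 <= np.median(alphas) <= 1.1


class TestPerTrackDiffusion:
    def test_zero_jumps_floored(self):
        traj = Trajectory(0, np.arange(10), np.zeros(10), np.zeros(10), 0.02)
        assert per_track_diffusion(traj, 0.0) == 1e-6

    def test_constant_jump_arithmetic(self):
        dt, r, sigma = 0.02, 0.1, 0.02
        x = np.arange(10) * r
        traj = Trajectory(0, np.arange(10), x, np.zeros(10), dt)
        expected = r**2 / (4 * dt) - sigma**2 / dt
        assert per_track_diffusion(traj, sigma) == pytest.approx(expected)

    def test_simulated_tracks_recover_d(self):
        rng = np.random.default_rng(4)
        sigma, d = 0.035, 0.2
        ds = [per_track_diffusion(brownian_track(rng, d, 40, sigma=sigma), sigma)
              for _ in range(500)]
        assert np.median(ds) == pytest.approx(d, rel=0.15)


class TestMobileSplit:
    def test_all_immobile(self):
        mobile, immobile = split_mobile_immobile([0.01] * 8)
        assert immobile == 1.0 and mobile == 0.0

    def test_threshold_at_median(self):
        ds = [0.01, 0.02, 0.5, 0.6]
        mobile, immobile = split_mobile_immobile(ds, d_threshold=0.1)
        assert mobile == immobile == 0.5

    def test_three_state_sim_bound_fraction(self):
        cfg = SmtSimConfig(n_molecules=2000, n_frames=30, bleach_rate=0.0,
                           seed=5)
        trajs, _ = simulate_trajectories(cfg)
        ds = [per_track_diffusion(t, cfg.loc_error_sd) for t in trajs
              if len(t) >= 5]
        _, immobile = split_mobile_immobile(ds, d_threshold=0.1)
        assert immobile == pytest.approx(0.3, abs=0.05)


class TestThreeStateFit:
    def test_single_state_degenerate_recovery(self):
        cfg = SmtSimConfig(n_molecules=2000, fractions=(1.0, 0.0, 0.0),
                           diffusion=(0.01, 0.15, 1.0), loc_error_sd=0.035,
                           seed=6)
        trajs, _ = simulate_trajectories(cfg)
        fit = fit_three_state(trajs, seed=1)
        assert fit.f_bound >= 0.95
        assert fit.sigma == pytest.approx(0.035, rel=0.20)

    def test_three_state_parameter_recovery(self):
        cfg = SmtSimConfig(n_molecules=5000, seed=7)
        trajs, _ = simulate_trajectories(cfg)
        fit = fit_three_state(trajs, seed=2)
        for got, want in zip(fit.fractions, (0.3, 0.3, 0.4)):
            assert abs(got - want) <= 0.05
        for got, want in zip(fit.diffusion, (0.01, 0.15, 1.0)):
            assert abs(got - want) / want <= 0.20

    def test_fractions_sum_to_one_and_bounds_respected(self):
        cfg = SmtSimConfig(n_molecules=1000, seed=8)
        trajs, _ = simulate_trajectories(cfg)
        fit = fit_three_state(trajs, n_init=4, seed=3)
        assert sum(fit.fractions) == pytest.approx(1.0, abs=1e-6)
        for d, key in zip(fit.diffusion, ("bound", "slow", "fast")):
            lo, hi = D_BOUNDS[key]
            assert lo <= d <= hi

    def test_reproducible_given_seed(self):
        cfg = SmtSimConfig(n_molecules=800, seed=9)
        trajs, _ = simulate_trajectories(cfg)
        f1 = fit_three_state(trajs, n_init=3, seed=4)
        f2 = fit_three_state(trajs, n_init=3, seed=4)
        assert f1.fractions == f2.fractions and f1.sse == f2.sse

    def test_too_few_jumps_rejected(self):
        traj = Trajectory(0, np.arange(6), np.zeros(6), np.zeros(6), 0.02)
        with pytest.raises(ValueError, match="jumps"):
            fit_three_state([traj])


class TestJumpAngles:
    def test_straight_line_all_forward(self):
        x = np.arange(10) * 0.2
        traj = Trajectory(0, np.arange(10), x, np.zeros(10), 0.02)
        angles = jump_angles(traj)
        assert np.allclose(angles, 0.0)

    def test_zigzag_all_reversals(self):
        x = np.array([0.0, 0.2, 0.0, 0.2, 0.0, 0.2])
        traj = Trajectory(0, np.arange(6), x, np.zeros(6), 0.02)
        angles = jump_angles(traj)
        assert np.allclose(angles, 180.0)

    def test_small_jumps_excluded(self):
        x = np.array([0.0, 0.05, 0.10, 0.15])  # 50 nm jumps < 125 nm cutoff
        traj = Trajectory(0, np.arange(4), x, np.zeros(4), 0.02)
        assert len(jump_angles(traj)) == 0

    def test_brownian_angles_uniform(self):
        rng = np.random.default_rng(10)
        angles = []
        while len(angles) < 10000:
            traj = brownian_track(rng, 1.0, 100)
            angles.extend(jump_angles(traj))
        angles = np.asarray(angles[:10000])
        p = stats.kstest(angles / 180.0, "uniform").pvalue
        assert p > 0.01


class TestAnisotropy:
    def test_uniform_angles_ratio_one(self):
        rng = np.random.default_rng(11)
        angles = rng.uniform(0, 180, size=20000)
        assert anisotropy(angles) == pytest.approx(1.0, abs=0.1)

    def test_zigzag_gives_inf_with_warning(self):
        with pytest.warns(UserWarning, match="forward"):
            assert anisotropy(np.full(50, 180.0)) == np.inf

    def test_trapped_molecules_increase_ratio(self):
        # alternate free flights with bound interludes that reverse direction
        rng = np.random.default_rng(12)
        angles = []
        for _ in range(300):
            n = 40
            x, y = [0.0], [0.0]
            trapped = False
            cx = 0.0
            for i in range(n - 1):
                if i % 10 == 0:
                    trapped = not trapped
                    cx = x[-1]
                if trapped:  # spring back toward trap centre: reversals
                    x.append(cx + rng.normal(0, 0.15))
                    y.append(y[-1] + rng.normal(0, 0.15))
                else:
                    x.append(x[-1] + rng.normal(0, 0.25))
                    y.append(y[-1] + rng.normal(0, 0.25))
            traj = Trajectory(0, np.arange(n), np.array(x), np.array(y), 0.02)
            angles.extend(jump_angles(traj))
        assert anisotropy(np.asarray(angles)) > 1.2


class TestConfinementRadius:
    def test_degenerate_track_zero(self):
        traj = Trajectory(0, np.arange(5), np.full(5, 1.0), np.full(5, 2.0), 0.02)
        assert confinement_radius(traj) == 0.0

    def test_square_geometry(self):
        x = np.array([0.0, 0.2, 0.2, 0.0, 0.0])
        y = np.array([0.0, 0.0, 0.2, 0.2, 0.0])
        traj = Trajectory(0, np.arange(5), x, y, 0.02)
        # centroid (0.08, 0.08); farthest corner (0.2, 0.2)
        assert confinement_radius(traj) == pytest.approx(
            np.hypot(0.12, 0.12), abs=1e-9
        )
        assert radius_of_gyration(traj) < confinement_radius(traj)

    def test_modal_radius_grows_with_track_length(self):
        rng = np.random.default_rng(13)
        sigma = 0.035

        def modal_r(n):
            rs = [confinement_radius(brownian_track(rng, 0.0, n, sigma=sigma))
                  for _ in range(300)]
            return np.median(rs)

        assert modal_r(10) < modal_r(50) < modal_r(200)


class TestCellFeaturesPca:
    def _cells(self, rng, d_values, n_tracks=40):
        out = []
        for i, d in enumerate(d_values):
            trajs = [brownian_track(rng, d, 30, sigma=0.02, track_id=j)
                     for j in range(n_tracks)]
            out.append(cell_features(trajs, cell_id=f"c{i}"))
        return out

    def test_identical_cells_at_origin(self):
        rng = np.random.default_rng(14)
        cell = self._cells(rng, [0.2])[0]
        coords, explained, names = features_pca([cell, cell, cell])
        assert np.allclose(coords, 0.0)

    def test_two_groups_separate_on_pc1(self):
        rng = np.random.default_rng(15)
        cells = self._cells(rng, [0.05] * 4 + [1.0] * 4)
        coords, explained, names = features_pca(cells)
        lo, hi = coords[:4, 0], coords[4:, 0]
        assert max(lo) < min(hi) or min(lo) > max(hi)
        assert 0 < explained.sum() <= 1.0 + 1e-9

    def test_pca_needs_three_cells(self):
        rng = np.random.default_rng(16)
        cells = self._cells(rng, [0.1, 0.2])
        with pytest.raises(ValueError, match="3 cells"):
            features_pca(cells)
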