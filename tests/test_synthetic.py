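"""Generators: determinism, analytic-MSD agreement, and parameter recovery."""

import numpy as np
import pytest

from condensage import (
    FrapGroundTruth,
    MotionModel,
    SimulationConfig,
    render_condensate_image,
    render_frames,
    simulate_frap,
    simulate_kinetics,
    simulate_tht,
    simulate_trajectories,
)
from condensage.synthetic.trajectories import fbm_increment_covariance


def empirical_msd(traj, max_lag):
    pos = traj.positions_array()
    out = []
    for k in range(1, max_lag + 1):
        d = pos[:, k:] - pos[:, :-k]
        out.append(np.mean(np.sum(d**2, axis=-1)))
    return np.array(out)


class TestDeterminism:
    def test_identical_seed_bitwise_identical(self):
        cfg = SimulationConfig(seed=11, n_particles=20, n_frames=30)
        m = MotionModel(kind="subdiffusive", alpha_true=0.5, K=0.5)
        a = simulate_trajectories(cfg, m).data
        b = simulate_trajectories(cfg, m).data
        assert a.equals(b)

    def test_different_seeds_differ(self):
        m = MotionModel(kind="newtonian", D=1.0)
        a = simulate_trajectories(SimulationConfig(seed=1, n_particles=5, n_frames=10), m)
        b = simulate_trajectories(SimulationConfig(seed=2, n_particles=5, n_frames=10), m)
        assert not np.allclose(a.positions_array(), b.positions_array())


class TestBrownian:
    def test_msd_first_lag_matches_4dt(self, brownian_ensemble_large):
        # analytic 4*D*tau at tau = dt with D = 1, dt = 0.02 -> 0.080 um^2
        msd = empirical_msd(brownian_ensemble_large, 1)
        assert msd[0] == pytest.approx(0.080, rel=0.02)

    def test_increment_variance(self, brownian_ensemble_large):
        pos = brownian_ensemble_large.positions_array()
        incr = np.diff(pos, axis=1)
        var = incr.var()
        expected = 2 * 1.0 * 0.02
        n = incr.size
        se = expected * np.sqrt(2 / n)
        assert abs(var - expected) < 3 * se

    def test_degenerate_zero_diffusion_is_motionless(self):
        cfg = SimulationConfig(seed=0, n_particles=3, n_frames=20)
        traj = simulate_trajectories(cfg, MotionModel(kind="newtonian", D=0.0))
        assert np.allclose(traj.positions_array(), 0.0)


class TestSubdiffusive:
    def test_covariance_oracle_consistent_with_fbm_variance(self):
        # summed increment covariance must equal Var[B_H(k dt)] = (k dt)^(2H)
        H, dt, n = 0.25, 0.02, 40
        cov = fbm_increment_covariance(n, H, dt)
        for k in (1, 5, 17, 40):
            var_k = cov[:k, :k].sum()
            assert var_k == pytest.approx((k * dt) ** (2 * H), rel=1e-10)

    def test_loglog_slope_matches_alpha(self):
        cfg = SimulationConfig(seed=3, n_particles=10_000, n_frames=60, dt=0.1)
        traj = simulate_trajectories(
            cfg, MotionModel(kind="subdiffusive", alpha_true=0.5, K=0.5)
        )
        msd = empirical_msd(traj, 10)  # lags 0.1 .. 1.0 s, one decade
        tau = np.arange(1, 11) * 0.1
        slope = np.polyfit(np.log(tau), np.log(msd), 1)[0]
        assert slope == pytest.approx(0.50, abs=0.05)

    def test_superdiffusive_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha_true"):
            MotionModel(kind="subdiffusive", alpha_true=1.2, K=1.0)


class TestJeffreys:
    def test_msd_matches_analytic_pointwise(self):
        model = MotionModel(kind="jeffreys", D_free=0.05, plateau=0.1, tau_relax=0.2)
        cfg = SimulationConfig(seed=5, n_particles=10_000, n_frames=40, dt=0.02)
        traj = simulate_trajectories(cfg, model)
        lags = np.arange(1, 11) * 0.02
        msd = empirical_msd(traj, 10)
        assert np.allclose(msd, model.analytic_msd(lags), rtol=0.05)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            ({"dt": 0.0}, "dt"),
            ({"n_frames": 1}, "n_frames"),
            ({"bead_radius": -1.0}, "bead_radius"),
            ({"temperature": 0.0}, "temperature"),
        ],
    )
    def test_invalid_fields_named_in_error(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            SimulationConfig(**kwargs)


class TestRenderFrames:
    def test_static_spot_centroid_matches_truth(self):
        cfg = SimulationConfig(seed=0, n_particles=1, n_frames=3, pixel_size=0.1)
        pos = np.tile([[1.03, 2.07]], (1, 3, 1)).reshape(1, 3, 2)
        from condensage.synthetic.trajectories import TrajectoryEnsemble

        traj = TrajectoryEnsemble.from_positions(pos, cfg.dt)
        stack = render_frames(traj, psf_sigma=0.15, snr=np.inf, config=cfg, shape=(40, 40))
        for frame in stack.images:
            img = frame.astype(float) - frame.min()
            yy, xx = np.mgrid[0:40, 0:40]
            cx = (img * xx).sum() / img.sum()
            cy = (img * yy).sum() / img.sum()
            assert cx == pytest.approx(10.3, abs=0.01)
            assert cy == pytest.approx(20.7, abs=0.01)

    def test_zero_particles_gives_background_stack(self):
        import pandas as pd

        from condensage.synthetic.trajectories import TRAJECTORY_COLUMNS, TrajectoryEnsemble

        empty = TrajectoryEnsemble(
            data=pd.DataFrame(columns=TRAJECTORY_COLUMNS), dt=0.02
        )
        cfg = SimulationConfig(seed=1, n_particles=1, n_frames=2)
        stack = render_frames(empty, 0.15, snr=10, config=cfg, shape=(32, 32), n_frames=4)
        assert stack.images.shape == (4, 32, 32)
        assert stack.images.mean() == pytest.approx(100.0, rel=0.05)

    def test_out_of_view_particle_rejected_with_location(self):
        cfg = SimulationConfig(seed=0, n_particles=1, n_frames=2, pixel_size=0.1)
        pos = np.array([[[1.0, 1.0], [99.0, 1.0]]])
        from condensage.synthetic.trajectories import TrajectoryEnsemble

        traj = TrajectoryEnsemble.from_positions(pos, cfg.dt)
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            render_frames(traj, 0.15, snr=10, config=cfg, shape=(32, 32))


class TestFrapGenerator:
    def test_full_recovery_no_drift_reaches_prebleach(self):
        truth = FrapGroundTruth(F_m_true=1.0, tau_half_true=0.5)
        rec = simulate_frap(truth, n_pre=2, n_post=50, dt=0.2, seed=0)
        t_post = rec.t[rec.bleach_frame:] - rec.t[rec.bleach_frame]
        assert rec.roi[rec.bleach_frame:][t_post >= 5.0].min() >= 0.99 * 1.0

    def test_fully_immobile_stays_at_bleached_level(self):
        truth = FrapGroundTruth(F_m_true=0.0, tau_half_true=1.0, bleach_depth=0.8)
        rec = simulate_frap(truth, n_pre=2, n_post=20, dt=1.0, seed=0)
        post = rec.roi[rec.bleach_frame:]
        assert np.allclose(post, post[0])

    def test_invalid_mobile_fraction_rejected(self):
        with pytest.raises(ValueError, match="F_m_true"):
            FrapGroundTruth(F_m_true=1.5, tau_half_true=1.0)


class TestPlateGenerators:
    def test_tht_midpoint_and_lower_asymptote(self):
        k, t_half = 0.5, 10.0
        t = np.sort(np.array([t_half - 20.0 / k, 0.0, t_half, 20.0, 30.0, 40.0]))
        s = simulate_tht(0.2, 1.2, k, t_half, t, noise_sd=0.0, seed=0)
        at_half = s.intensity[s.t == t_half][0]
        assert at_half == pytest.approx((0.2 + 1.2) / 2, abs=1e-12)
        at_floor = s.intensity[s.t == t_half - 20.0 / k][0]
        assert abs(at_floor - 0.2) < 1e-4

    def test_tht_rejects_imax_below_i0(self):
        with pytest.raises(ValueError, match="Imax"):
            simulate_tht(1.0, 0.5, 1.0, 10.0, np.arange(5.0))

    def test_kinetics_half_saturation_slope(self):
        ds = simulate_kinetics(
            kcat=20.0, K_M=40.0, E0=1.0, S_grid=np.array([40.0]),
            t_grid=np.linspace(0, 1, 11), noise_sd=0.0,
        )
        slope = np.polyfit(ds.t, ds.conc[:, 0], 1)[0]
        assert slope == pytest.approx(10.0, rel=1e-9)  # kcat*E0/2

    def test_kinetics_saturation_limit(self):
        ds = simulate_kinetics(
            kcat=20.0, K_M=40.0, E0=1.0, S_grid=np.array([40_000.0]),
            t_grid=np.linspace(0, 1, 11), noise_sd=0.0,
        )
        slope = np.polyfit(ds.t, ds.conc[:, 0], 1)[0]
        assert slope == pytest.approx(20.0, rel=1e-3)


class TestCondensateImageGenerator:
    def test_interior_exterior_ratio_is_exact_without_noise(self):
        img = render_condensate_image(5, cargo_in_out=3.0, noise_sd=0.0, seed=2)
        labels = img.ground_truth["label_map"]
        inside = img.cargo_channel[labels > 0].mean()
        outside = img.cargo_channel[labels == 0].mean()
        assert inside / outside == pytest.approx(3.0, rel=1e-12)

    def test_overcrowded_field_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            render_condensate_image(500, radius_px=20, shape=(128, 128))
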