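"""Spot detection and trajectory linking against ground truth and a
brute-force minimum-cost matching oracle."""

import itertools

import numpy as np
import pytest

from condensage import (
    LinkingParams,
    Localization,
    MotionModel,
    SimulationConfig,
    compute_msd,
    detect_spots,
    link_trajectories,
    render_frames,
    simulate_trajectories,
)
from condensage.synthetic.frames import FrameStack
from condensage.synthetic.trajectories import TrajectoryEnsemble


def brute_force_matching(prev, curr, max_disp):
    """Exhaustive matching oracle: maximum cardinality, then minimum total
    squared displacement, over all gated pairings."""
    n, m = len(prev), len(curr)
    for size in range(min(n, m), -1, -1):
        best = None
        for cs in itertools.combinations(range(n), size):
            for ps in itertools.permutations(range(m), size):
                cost, ok = 0.0, True
                for a, b in zip(cs, ps):
                    d = (prev[a][0] - curr[b][0]) ** 2 + (prev[a][1] - curr[b][1]) ** 2
                    if d > max_disp**2:
                        ok = False
                        break
                    cost += d
                if ok and (best is None or cost < best[1]):
                    best = (list(zip(cs, ps)), cost)
        if best is not None:
            return best
    return [], 0.0


def single_frame_stack(img, pixel_size=0.1, dt=0.02):
    return FrameStack(images=img[None].astype(np.uint16), pixel_size_um=pixel_size, dt_s=dt)


class TestDetectSpots:
    def test_subpixel_localization_of_noiseless_spot(self):
        cfg = SimulationConfig(seed=0, n_particles=1, n_frames=2, pixel_size=0.1)
        pos = np.tile([[1.03, 2.07]], (1, 2, 1)).reshape(1, 2, 2)
        traj = TrajectoryEnsemble.from_positions(pos, cfg.dt)
        stack = render_frames(traj, psf_sigma=0.15, snr=np.inf, config=cfg, shape=(40, 40))
        locs = detect_spots(stack, spot_sigma=1.5)
        assert len(locs) == 2  # one per frame
        for loc in locs:
            assert loc.x == pytest.approx(10.3, abs=0.05)
            assert loc.y == pytest.approx(20.7, abs=0.05)

    def test_pure_background_yields_no_spots(self):
        import pandas as pd

        from condensage.synthetic.trajectories import TRAJECTORY_COLUMNS

        empty = TrajectoryEnsemble(data=pd.DataFrame(columns=TRAJECTORY_COLUMNS), dt=0.02)
        cfg = SimulationConfig(seed=13, n_particles=1, n_frames=2)
        stack = render_frames(empty, 0.15, snr=10, config=cfg, shape=(64, 64), n_frames=5)
        assert detect_spots(stack, spot_sigma=1.5) == []

    def test_two_well_separated_spots(self):
        cfg = SimulationConfig(seed=0, n_particles=2, n_frames=2, pixel_size=0.1)
        pos = np.array(
            [[[1.0, 1.0], [1.0, 1.0]], [[4.5, 4.5], [4.5, 4.5]]]
        )  # 35 px apart >> 10 sigma
        traj = TrajectoryEnsemble.from_positions(pos, cfg.dt)
        stack = render_frames(traj, psf_sigma=0.15, snr=np.inf, config=cfg, shape=(64, 64))
        locs = detect_spots(stack, spot_sigma=1.5)
        assert len([l for l in locs if l.frame == 0]) == 2

    def test_empty_stack_rejected(self):
        stack = FrameStack(images=np.empty((0, 8, 8), np.uint16), pixel_size_um=0.1, dt_s=0.02)
        with pytest.raises(ValueError, match="empty"):
            detect_spots(stack, spot_sigma=1.5)


class TestLinking:
    def params(self, **kw):
        defaults = dict(max_displacement=3.0, memory=0, min_track_length=2)
        defaults.update(kw)
        return LinkingParams(**defaults)

    def test_two_distant_particles_no_identity_swap(self):
        locs = []
        for f in range(10):
            locs.append(Localization(f, 5.0 + 0.1 * f, 5.0, 1.0))
            locs.append(Localization(f, 30.0, 30.0 + 0.1 * f, 1.0))
        traj = link_trajectories(locs, self.params(), 0.1, 0.02)
        assert traj.n_particles == 2
        for _, g in traj.data.groupby("particle"):
            assert len(g) == 10
            assert g[["x_um", "y_um"]].std().max() < 0.2  # no jump between corners

    def test_gap_bridged_by_memory(self):
        locs = [Localization(f, 10.0 + 0.2 * f, 10.0, 1.0) for f in range(10) if f != 4]
        traj = link_trajectories(locs, self.params(memory=1), 0.1, 0.02)
        assert traj.n_particles == 1
        assert len(traj.data) == 9

    def test_gap_not_bridged_without_memory(self):
        locs = [Localization(f, 10.0 + 0.2 * f, 10.0, 1.0) for f in range(10) if f != 4]
        traj = link_trajectories(locs, self.params(memory=0), 0.1, 0.02)
        assert traj.n_particles == 2

    def test_close_encounter_matches_brute_force_oracle(self):
        prev = [(10.0, 10.0), (12.0, 10.0)]
        curr = [(11.1, 10.0), (12.9, 10.0)]  # both within reach of both
        locs = [Localization(0, x, y, 1.0) for x, y in prev] + [
            Localization(1, x, y, 1.0) for x, y in curr
        ]
        traj = link_trajectories(locs, self.params(max_displacement=3.0), 1.0, 1.0)
        oracle, _ = brute_force_matching(prev, curr, 3.0)
        assert traj.n_particles == 2
        # reconstruct the implementation's assignment
        got = []
        for _, g in traj.data.groupby("particle"):
            g = g.sort_values("frame")
            a = prev.index((g.iloc[0].x_um, g.iloc[0].y_um))
            b = curr.index((g.iloc[1].x_um, g.iloc[1].y_um))
            got.append((a, b))
        assert sorted(got) == sorted(oracle)

    def test_short_tracks_dropped(self):
        locs = [Localization(0, 5.0, 5.0, 1.0)]  # singleton
        traj = link_trajectories(locs, self.params(min_track_length=2), 0.1, 0.02)
        assert traj.n_particles == 0

    def test_no_duplicate_assignment_within_frame(self):
        rng = np.random.default_rng(0)
        locs = []
        for f in range(6):
            for x, y in rng.uniform(5, 55, (8, 2)):
                locs.append(Localization(f, float(x), float(y), 1.0))
        traj = link_trajectories(locs, self.params(max_displacement=50.0), 0.1, 0.02)
        dup = traj.data.groupby(["particle", "frame"]).size()
        assert (dup == 1).all()


class TestRoundTrip:
    def test_tracking_recovers_ground_truth_msd(self):
        # probes laid out on a grid so spots never overlap, as in a real
        # bead-tracking field
        cfg = SimulationConfig(seed=9, n_particles=10, n_frames=100, dt=0.02,
                               pixel_size=0.1)
        base = simulate_trajectories(cfg, MotionModel(kind="newtonian", D=0.05))
        starts = np.array(
            [[2.0 + (i % 4) * 2.9, 2.2 + (i // 4) * 3.2] for i in range(10)]
        )
        traj = TrajectoryEnsemble.from_positions(
            base.positions_array() + starts[:, None, :], cfg.dt
        )
        stack = render_frames(traj, psf_sigma=0.15, snr=10, config=cfg,
                              shape=(128, 128))
        locs = detect_spots(stack, spot_sigma=1.5, threshold_sd=5)
        linked = link_trajectories(
            locs, LinkingParams(max_displacement=5, memory=1, min_track_length=50),
            pixel_size=0.1, dt=0.02,
        )
        assert linked.n_particles == 10
        m_true = compute_msd(traj, 0.25)
        m_est = compute_msd(linked, 0.25)
        n = min(len(m_true.lag), len(m_est.lag), 12)
        diffs = m_est.msd[:n] - m_true.msd[:n]
        # localization noise adds a constant 4*sigma_loc^2 offset
        offset = np.median(diffs)
        assert offset > 0 and np.all(diffs > 0)
        assert np.allclose(m_est.msd[:n] - offset, m_true.msd[:n],
                           rtol=0.05, atol=2e-4)

    def test_track_count_bounded_by_max_localizations_per_frame(self):
        cfg = SimulationConfig(seed=2, n_particles=5, n_frames=30, dt=0.02,
                               pixel_size=0.1)
        traj = simulate_trajectories(
            cfg, MotionModel(kind="newtonian", D=0.02),
            start_box=((1.5, 4.9), (1.5, 4.9)),
        )
        stack = render_frames(traj, psf_sigma=0.15, snr=10, config=cfg, shape=(64, 64))
        locs = detect_spots(stack, spot_sigma=1.5)
        per_frame = max(
            len([l for l in locs if l.frame == f]) for f in range(stack.n_frames)
        )
        linked = link_trajectories(
            locs, LinkingParams(max_displacement=5, memory=2, min_track_length=2),
            pixel_size=0.1, dt=0.02,
        )
        assert linked.n_particles <= per_frame + 5  # new tracks from misses only
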