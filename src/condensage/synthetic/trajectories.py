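"""Synthetic probe-particle trajectories with known ground truth.

Three motion models cover the material states a condensate traverses while it
ages:

* ``newtonian`` — ordinary Brownian motion in a viscous fluid,
  MSD(tau) = 4*D*tau (2D).
* ``subdiffusive`` — fractional Brownian motion with Hurst index
  H = alpha/2 per axis, the minimal stationary-increment Gaussian process with
  MSD(tau) = 4*K*tau**alpha, emulating a viscoelastic medium.
* ``jeffreys`` — free diffusion plus a saturating confinement term,
  MSD(tau) = 4*D_free*tau + plateau*(1 - exp(-tau/tau_relax)); its moduli show
  exactly one storage/loss crossover, i.e. a Maxwell-fluid phenotype.

Localization noise is additive Gaussian on positions (the standard tracking
error model); it inflates the MSD by a constant 4*sigma**2 offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .._rng import child_rng

__all__ = [
    "SimulationConfig",
    "MotionModel",
    "TrajectoryEnsemble",
    "simulate_trajectories",
    "fbm_increment_covariance",
]

TRAJECTORY_COLUMNS = ["particle", "frame", "t_s", "x_um", "y_um"]


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition geometry and physics shared by all trajectory simulations.

    Defaults mirror a spinning-disk acquisition of 100 nm-radius fluorescent
    beads at 50 frames per second for 200 frames at room temperature.
    """

    seed: int = 0
    n_particles: int = 100
    n_frames: int = 200
    dt: float = 0.02  # s
    pixel_size: float = 0.1  # um / pixel
    bead_radius: float = 0.1  # um
    temperature: float = 298.15  # K
    localization_noise_sd: float = 0.0  # um

    def __post_init__(self) -> None:
        _require_positive("dt", self.dt)
        _require_positive("pixel_size", self.pixel_size)
        _require_positive("bead_radius", self.bead_radius)
        _require_positive("temperature", self.temperature)
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")
        if self.n_particles < 1:
            raise ValueError(f"n_particles must be >= 1, got {self.n_particles}")
        if self.localization_noise_sd < 0:
            raise ValueError("localization_noise_sd must be >= 0")


@dataclass(frozen=True)
class MotionModel:
    """Ground-truth motion law for a probe ensemble.

    Parameters are interpreted according to ``kind``:

    newtonian
        ``D`` [um^2/s]; MSD = 4*D*tau.
    subdiffusive
        ``alpha_true`` (0, 1] and ``K`` [um^2/s^alpha]; MSD = 4*K*tau**alpha.
    jeffreys
        ``D_free`` [um^2/s], ``plateau`` [um^2], ``tau_relax`` [s];
        MSD = 4*D_free*tau + plateau*(1 - exp(-tau/tau_relax)).
    """

    kind: Literal["newtonian", "subdiffusive", "jeffreys"]
    D: float | None = None
    alpha_true: float | None = None
    K: float | None = None
    D_free: float | None = None
    plateau: float | None = None
    tau_relax: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "newtonian":
            if self.D is None or self.D < 0:
                raise ValueError("newtonian model requires D >= 0")
        elif self.kind == "subdiffusive":
            if self.alpha_true is None or not 0 < self.alpha_true <= 1:
                raise ValueError(
                    "subdiffusive model requires 0 < alpha_true <= 1 "
                    "(superdiffusion unsupported)"
                )
            if self.K is None or not self.K > 0:
                raise ValueError("subdiffusive model requires K > 0")
        elif self.kind == "jeffreys":
            for name in ("D_free", "plateau", "tau_relax"):
                v = getattr(self, name)
                if v is None or not v > 0:
                    raise ValueError(f"jeffreys model requires {name} > 0")
        else:
            raise ValueError(f"unknown motion model kind {self.kind!r}")

    def analytic_msd(self, tau: np.ndarray) -> np.ndarray:
        """Ground-truth 2D ensemble MSD at lag times ``tau`` (noise-free)."""
        tau = np.asarray(tau, dtype=float)
        if self.kind == "newtonian":
            return 4.0 * self.D * tau
        if self.kind == "subdiffusive":
            return 4.0 * self.K * tau**self.alpha_true
        return 4.0 * self.D_free * tau + self.plateau * (
            1.0 - np.exp(-tau / self.tau_relax)
        )


@dataclass
class TrajectoryEnsemble:
    """Per-particle 2D positions over uniformly sampled frames.

    ``data`` holds long-format columns ``particle, frame, t_s, x_um, y_um``;
    tracks may have unequal lengths and gaps (after linking), but sampling is
    uniform with interval ``dt``.
    """

    data: pd.DataFrame
    dt: float
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in TRAJECTORY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trajectory table missing columns {missing}")

    @property
    def n_particles(self) -> int:
        return self.data["particle"].nunique()

    def positions_array(self) -> np.ndarray:
        """Dense (n_particles, n_frames, 2) array; only valid for gap-free
        equal-length ensembles (as produced by the simulators)."""
        counts = self.data.groupby("particle").size()
        if counts.nunique() != 1:
            raise ValueError("ensemble is ragged; dense array unavailable")
        n = counts.iloc[0]
        ordered = self.data.sort_values(["particle", "frame"])
        return ordered[["x_um", "y_um"]].to_numpy().reshape(-1, n, 2)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, dt: float | None = None) -> "TrajectoryEnsemble":
        df = pd.read_csv(path)
        if dt is None:
            t = np.sort(df["t_s"].unique())
            if len(t) < 2:
                raise ValueError("cannot infer dt from a single time point")
            dt = float(np.min(np.diff(t)))
        return cls(data=df, dt=float(dt))

    @classmethod
    def from_positions(
        cls, positions: np.ndarray, dt: float, ground_truth: dict | None = None
    ) -> "TrajectoryEnsemble":
        positions = np.asarray(positions, dtype=float)
        n_particles, n_frames, _ = positions.shape
        particle = np.repeat(np.arange(n_particles), n_frames)
        frame = np.tile(np.arange(n_frames), n_particles)
        df = pd.DataFrame(
            {
                "particle": particle,
                "frame": frame,
                "t_s": frame * dt,
                "x_um": positions[..., 0].ravel(),
                "y_um": positions[..., 1].ravel(),
            }
        )
        return cls(data=df, dt=dt, ground_truth=ground_truth or {})


def fbm_increment_covariance(n_steps: int, hurst: float, dt: float) -> np.ndarray:
    """Exact covariance matrix of fractional Gaussian noise (unit scale).

    gamma(k) = 0.5*(|k+1|^(2H) - 2|k|^(2H) + |k-1|^(2H)) * dt^(2H), the
    stationary increment covariance of fBm with Var[B_H(t)] = t^(2H).
    """
    k = np.arange(n_steps, dtype=float)
    two_h = 2.0 * hurst
    gamma = 0.5 * ((k + 1) ** two_h - 2 * k**two_h + np.abs(k - 1) ** two_h)
    gamma *= dt**two_h
    idx = np.abs(np.subtract.outer(np.arange(n_steps), np.arange(n_steps)))
    return gamma[idx]


def _sample_fbm_increments(
    rng: np.random.Generator, n_paths: int, n_steps: int, hurst: float, dt: float
) -> np.ndarray:
    """Draw (n_paths, n_steps) exact fGn via Cholesky of the full covariance."""
    cov = fbm_increment_covariance(n_steps, hurst, dt)
    # jitter guards against loss of positive definiteness at H -> 0
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(n_steps))
    z = rng.standard_normal((n_steps, n_paths))
    return (L @ z).T


def simulate_trajectories(
    config: SimulationConfig,
    model: MotionModel,
    start_box: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> TrajectoryEnsemble:
    """Simulate an ensemble of 2D probe trajectories under ``model``.

    Positions start at the origin (the MSD is translation invariant) unless
    ``start_box`` gives ((xmin, xmax), (ymin, ymax)) in um, in which case
    start positions are drawn uniformly within it — needed when the ensemble
    is to be rendered into a field of view.  Localization noise of sd
    ``config.localization_noise_sd`` is added independently per frame and
    axis.  The returned ensemble carries its ground truth in ``ground_truth``
    for test consumption only.
    """
    rng = child_rng(config.seed, "trajectories")
    n, m = config.n_particles, config.n_frames
    steps = m - 1

    if model.kind == "newtonian":
        # i.i.d. Gaussian increments, per-axis variance 2*D*dt
        sd = np.sqrt(2.0 * model.D * config.dt)
        incr = rng.standard_normal((n, steps, 2)) * sd
    elif model.kind == "subdiffusive":
        # per-axis fBm with H = alpha/2 and scale 2K: per-axis MSD = 2K tau^alpha
        hurst = model.alpha_true / 2.0
        scale = np.sqrt(2.0 * model.K)
        incr = np.empty((n, steps, 2))
        for axis in range(2):
            incr[:, :, axis] = scale * _sample_fbm_increments(
                rng, n, steps, hurst, config.dt
            )
    else:  # jeffreys: Brownian + stationary Ornstein-Uhlenbeck confinement
        sd_b = np.sqrt(2.0 * model.D_free * config.dt)
        brown = np.cumsum(rng.standard_normal((n, steps, 2)) * sd_b, axis=1)
        brown = np.concatenate([np.zeros((n, 1, 2)), brown], axis=1)
        sigma2 = model.plateau / 4.0  # per-axis stationary variance
        rho = np.exp(-config.dt / model.tau_relax)
        ou = np.empty((n, m, 2))
        ou[:, 0] = rng.standard_normal((n, 2)) * np.sqrt(sigma2)
        kick_sd = np.sqrt(sigma2 * (1.0 - rho**2))
        kicks = rng.standard_normal((n, steps, 2)) * kick_sd
        for j in range(steps):  # exact OU update
            ou[:, j + 1] = ou[:, j] * rho + kicks[:, j]
        pos = brown + ou - ou[:, :1]  # start at origin
        return _finalize(pos, config, model, rng, start_box)

    pos = np.concatenate([np.zeros((n, 1, 2)), np.cumsum(incr, axis=1)], axis=1)
    return _finalize(pos, config, model, rng, start_box)


def _finalize(
    pos: np.ndarray,
    config: SimulationConfig,
    model: MotionModel,
    rng: np.random.Generator,
    start_box: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> TrajectoryEnsemble:
    if start_box is not None:
        (xlo, xhi), (ylo, yhi) = start_box
        starts = np.column_stack(
            [
                rng.uniform(xlo, xhi, pos.shape[0]),
                rng.uniform(ylo, yhi, pos.shape[0]),
            ]
        )
        pos = pos + starts[:, None, :]
    if config.localization_noise_sd > 0:
        pos = pos + rng.standard_normal(pos.shape) * config.localization_noise_sd
    truth = {"model": model, "config": config}
    return TrajectoryEnsemble.from_positions(pos, config.dt, ground_truth=truth)
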