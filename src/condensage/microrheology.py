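"""Passive particle-tracking microrheology.

From an ensemble of probe trajectories this module computes the time- and
ensemble-averaged mean-squared displacement

    <dr^2(tau)> = <(r(tau) - r(0))^2> = 4 * D_app * tau**alpha(tau),

the diffusive exponent alpha(tau) = d ln<dr^2>/d ln tau, the viscoelastic
moduli via the generalized Stokes-Einstein relation (GSER)

    |G*(omega=1/tau)| = 2 kB T / (C * a * <dr^2(1/omega)> * Gamma[1 + alpha]),
    G'(omega) = |G*| cos(pi alpha / 2),   G''(omega) = |G*| sin(pi alpha / 2),

and the material state of the medium: viscous (G'' > G' everywhere),
elastic (G' > G'' everywhere), or a Maxwell fluid with a single crossover
frequency omega_c and relaxation time tau_c = 1/omega_c.

GSER prefactor modes
--------------------
``stokes_einstein_consistent`` (default) uses C = 3*pi, the Mason prefactor
consistent with a two-dimensional MSD: on a Newtonian fluid it returns
G''(omega) = eta * omega exactly.  ``literal`` uses C = 1, i.e. the bare
2 kB T / (a <dr^2> Gamma) form, provided for side-by-side comparison; on the
same fluid it yields 3*pi*eta*omega.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.constants import k as BOLTZMANN  # J/K
from scipy.ndimage import median_filter
from scipy.special import gamma as gamma_fn

from .synthetic.trajectories import TrajectoryEnsemble

__all__ = [
    "MsdCurve",
    "PowerLawFit",
    "GserParams",
    "ModuliCurve",
    "MaterialState",
    "compute_msd",
    "fit_powerlaw",
    "gser_moduli",
    "find_crossover",
    "classify_timecourse",
]


@dataclass
class MsdCurve:
    """Ensemble-averaged MSD on a uniform lag grid."""

    lag: np.ndarray  # s, strictly increasing
    msd: np.ndarray  # um^2
    n_pairs: np.ndarray  # displacement pairs contributing per lag
    max_lag_fraction: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lag) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd must be non-negative")


@dataclass
class PowerLawFit:
    """Long-time diffusive exponent and apparent diffusivity of an MSD."""

    alpha: float
    D_app: float  # um^2/s^alpha
    alpha_local: np.ndarray  # alpha(tau) on the MSD lag grid
    fit_window: tuple[float, float]  # s


@dataclass(frozen=True)
class GserParams:
    """Probe and bath parameters entering the GSER."""

    bead_radius: float = 0.1  # um
    temperature: float = 298.15  # K
    prefactor_mode: Literal["stokes_einstein_consistent", "literal"] = (
        "stokes_einstein_consistent"
    )

    def __post_init__(self) -> None:
        if not self.bead_radius > 0:
            raise ValueError("bead_radius must be > 0")
        if not self.temperature > 0:
            raise ValueError("temperature must be > 0")


@dataclass
class ModuliCurve:
    """Storage and loss moduli on the frequency grid omega = 1/tau."""

    omega: np.ndarray  # rad/s, strictly increasing
    G_storage: np.ndarray  # Pa
    G_loss: np.ndarray  # Pa
    alpha_at_omega: np.ndarray


@dataclass
class MaterialState:
    """Material-state call: viscous, maxwell (with crossover) or elastic."""

    state: Literal["viscous", "maxwell", "elastic"]
    omega_c: float | None = None  # rad/s
    tau_c: float | None = None  # s, = 1/omega_c

    def __post_init__(self) -> None:
        if (self.state == "maxwell") != (self.omega_c is not None):
            raise ValueError("omega_c present iff state is maxwell")


def compute_msd(traj: TrajectoryEnsemble, max_lag_fraction: float = 0.25) -> MsdCurve:
    """Time-averaged MSD per trajectory over all overlapping pairs, then
    ensemble-averaged weighted by pair counts.

    Lags are retained up to ``max_lag_fraction`` of the longest track; beyond
    that the time average rests on too few pairs to be reliable.
    """
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction must be in (0, 1]")
    df = traj.data
    if df.empty:
        raise ValueError("empty trajectory ensemble")
    dt = traj.dt

    max_len = 0
    tracks: list[tuple[np.ndarray, np.ndarray]] = []
    for _, g in df.groupby("particle", sort=True):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy(dtype=int)
        if len(frames) < 2:
            continue
        t = g["t_s"].to_numpy()
        rel = np.round(np.diff(t) / dt)
        if not np.allclose(np.diff(t), rel * dt, rtol=1e-6, atol=1e-9):
            raise ValueError("non-uniform sampling in trajectory table")
        tracks.append((frames - frames[0], g[["x_um", "y_um"]].to_numpy()))
        max_len = max(max_len, frames[-1] - frames[0] + 1)
    if not tracks:
        raise ValueError("need at least one trajectory of >= 2 frames")

    max_lag = max(1, int(np.floor(max_lag_fraction * (max_len - 1))))
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=np.int64)
    for frames, pos in tracks:
        # frames may have gaps (after linking with memory); use a dense array
        dense = np.full((frames[-1] + 1, 2), np.nan)
        dense[frames] = pos
        for k in range(1, min(max_lag, frames[-1]) + 1):
            d = dense[k:] - dense[:-k]
            sq = np.einsum("ij,ij->i", d, d)
            ok = ~np.isnan(sq)
            sums[k - 1] += sq[ok].sum()
            counts[k - 1] += ok.sum()

    keep = counts > 0
    lags = np.arange(1, max_lag + 1)[keep] * dt
    return MsdCurve(
        lag=lags,
        msd=sums[keep] / counts[keep],
        n_pairs=counts[keep],
        max_lag_fraction=max_lag_fraction,
    )


def _local_loglog_slope(log_tau: np.ndarray, log_msd: np.ndarray, half: int = 3) -> np.ndarray:
    """alpha(tau) by quadratic log-log fit over a sliding (2*half+1)-point window."""
    n = len(log_tau)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        x, y = log_tau[lo:hi], log_msd[lo:hi]
        deg = 2 if len(x) >= 4 else 1
        coeff = np.polyfit(x, y, deg)
        out[i] = np.polyval(np.polyder(coeff), log_tau[i])
    return out


def fit_powerlaw(
    msd: MsdCurve, window: tuple[float, float] | None = None
) -> PowerLawFit:
    """Fit <dr^2(tau)> = 4 * D_app * tau**alpha in log-log space.

    ``window`` restricts the global fit to a lag range [s]; default is the
    full retained range.  The local exponent alpha(tau) is estimated on the
    whole grid by a 7-point sliding quadratic fit (Mason smoothing).
    """
    if window is None:
        window = (float(msd.lag[0]), float(msd.lag[-1]))
    lo, hi = window
    sel = (msd.lag >= lo) & (msd.lag <= hi)
    if sel.sum() < 4:
        raise ValueError("fit window must contain >= 4 lags")
    if np.any(msd.msd[sel] <= 0):
        raise ValueError("msd contains zeros in the fit window; log undefined")
    if np.any(msd.msd <= 0):
        # local exponent needs logs everywhere; restrict grid to positive msd
        pos = msd.msd > 0
        msd = MsdCurve(msd.lag[pos], msd.msd[pos], msd.n_pairs[pos], msd.max_lag_fraction)
        sel = (msd.lag >= lo) & (msd.lag <= hi)

    log_tau = np.log(msd.lag)
    log_msd = np.log(msd.msd)
    alpha_local = _local_loglog_slope(log_tau, log_msd)
    slope, intercept = np.polyfit(log_tau[sel], log_msd[sel], 1)
    return PowerLawFit(
        alpha=float(slope),
        D_app=float(np.exp(intercept) / 4.0),
        alpha_local=alpha_local,
        fit_window=(lo, hi),
    )


def gser_moduli(msd: MsdCurve, fit: PowerLawFit, params: GserParams) -> ModuliCurve:
    """Viscoelastic moduli from the MSD via the generalized Stokes-Einstein
    relation, evaluated at omega = 1/tau on the retained lag grid.

    Output is in Pa (kB*T in J, bead radius and MSD converted to m, m^2).
    The local exponent is clamped to [0, 1] before the phase factor: the probe
    regime is sub- to normal-diffusive, and alpha > 1 would produce G' < 0.
    """
    if len(fit.alpha_local) != len(msd.lag):
        raise ValueError("fit.alpha_local must align with the MSD lag grid")
    nonzero = msd.msd > 0
    if not nonzero.all():
        warnings.warn(
            f"dropping {np.count_nonzero(~nonzero)} zero-MSD lags from the moduli",
            stacklevel=2,
        )
    lag = msd.lag[nonzero]
    msd_m2 = msd.msd[nonzero] * 1e-12  # um^2 -> m^2
    alpha = fit.alpha_local[nonzero]
    if np.any(alpha < 0):
        warnings.warn("alpha < 0 after smoothing; clamping to 0", stacklevel=2)
    alpha = np.clip(alpha, 0.0, 1.0)

    a_m = params.bead_radius * 1e-6
    C = 3.0 * np.pi if params.prefactor_mode == "stokes_einstein_consistent" else 1.0
    g_mag = (2.0 * BOLTZMANN * params.temperature) / (
        C * a_m * msd_m2 * gamma_fn(1.0 + alpha)
    )
    phase = np.pi * alpha / 2.0
    omega = 1.0 / lag
    order = np.argsort(omega)
    return ModuliCurve(
        omega=omega[order],
        G_storage=(g_mag * np.cos(phase))[order],
        G_loss=(g_mag * np.sin(phase))[order],
        alpha_at_omega=alpha[order],
    )


def find_crossover(moduli: ModuliCurve) -> MaterialState:
    """Classify the medium from the sign pattern of log G' - log G''.

    After a 3-point median smoothing: all negative -> viscous; all positive ->
    elastic; a single sign change with G'' dominant at low frequency ->
    Maxwell fluid, with omega_c interpolated in log-log and tau_c = 1/omega_c.
    Multiple crossings fall back to the lowest-frequency one with a warning.
    """
    if len(moduli.omega) < 4:
        raise ValueError("need >= 4 frequencies to classify")
    with np.errstate(divide="ignore"):
        delta = np.log(moduli.G_storage) - np.log(moduli.G_loss)
    delta = np.where(np.isfinite(delta), delta, np.sign(moduli.G_storage - moduli.G_loss) * 50.0)
    delta = median_filter(delta, size=3, mode="nearest")

    if np.all(delta < 0):
        return MaterialState(state="viscous")
    if np.all(delta > 0):
        return MaterialState(state="elastic")

    sign = np.sign(delta)
    sign[sign == 0] = 1.0
    flips = np.nonzero(np.diff(sign) != 0)[0]
    if len(flips) > 1:
        warnings.warn(
            "multiple storage/loss crossings after smoothing; "
            "using the lowest-frequency one",
            stacklevel=2,
        )
    if delta[0] > 0:  # G' dominant at low omega: not an aging Maxwell signature
        # treat as elastic-dominated with a reverse crossing; report elastic
        # unless the high-frequency side is clearly viscous (rare, noisy data)
        warnings.warn(
            "G' > G'' at low frequency with a crossing; reporting elastic",
            stacklevel=2,
        )
        return MaterialState(state="elastic")

    i = flips[0]
    log_w = np.log(moduli.omega)
    # linear interpolation of delta(log omega) across the sign change
    w_c = np.exp(
        log_w[i] - delta[i] * (log_w[i + 1] - log_w[i]) / (delta[i + 1] - delta[i])
    )
    return MaterialState(state="maxwell", omega_c=float(w_c), tau_c=float(1.0 / w_c))


#: the canonical aging path of a liquid condensate solidifying over time
_AGING_ORDER = {"viscous": 0, "maxwell": 1, "elastic": 2}


def classify_timecourse(states: Sequence[MaterialState]) -> dict:
    """Summarize an age-ordered sequence of material states.

    ``consistent`` is True when the sequence is monotone along the
    viscous -> maxwell -> elastic aging path.
    """
    if not states:
        raise ValueError("need at least one state")
    names = [s.state for s in states]
    ranks = [_AGING_ORDER[n] for n in names]
    consistent = all(b >= a for a, b in zip(ranks, ranks[1:]))
    return {"sequence": names, "consistent": consistent}
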