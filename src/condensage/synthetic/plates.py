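"""Synthetic plate-reader time series: ThT aggregation curves and enzyme
progress curves with known kinetic parameters."""

from __future__ import annotations

import numpy as np

from .._rng import child_rng
from ..kinetics import KineticsDataset, ThTSeries

__all__ = ["simulate_tht", "simulate_kinetics"]


def simulate_tht(
    I0: float,
    Imax: float,
    k: float,
    t_half: float,
    t_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ThTSeries:
    """Logistic ThT fluorescence curve,
    I(t) = I0 + (Imax - I0)/(1 + exp(-k (t - t_half))), plus Gaussian noise.
    """
    if not Imax > I0:
        raise ValueError("Imax must exceed I0")
    if not k > 0:
        raise ValueError("growth rate k must be > 0")
    t = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    y = I0 + (Imax - I0) / (1.0 + np.exp(-k * (t - t_half)))
    if noise_sd > 0:
        y = y + child_rng(seed, "tht").normal(0, noise_sd, len(t))
    return ThTSeries(
        t=t,
        intensity=y,
        ground_truth={"I0": I0, "Imax": Imax, "k": k, "t_half": t_half},
    )


def simulate_kinetics(
    kcat: float,
    K_M: float,
    E0: float,
    S_grid: np.ndarray,
    t_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    standard_curve_slope: float = 0.01,
    blank: float = 0.05,
) -> KineticsDataset:
    """Early-time product traces at several substrate concentrations.

    Within the initial-rate regime (substrate depletion negligible over
    ``t_grid``) product grows linearly at v = kcat*E0*S/(K_M + S).  The
    matching absorbance trace is emitted through the standard-curve relation
    A = slope * conc + blank.
    """
    for name, v in (("kcat", kcat), ("K_M", K_M), ("E0", E0)):
        if not v > 0:
            raise ValueError(f"{name} must be > 0")
    S = np.asarray(S_grid, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    if S.size == 0 or t.size == 0:
        raise ValueError("S_grid and t_grid must be non-empty")
    rng = child_rng(seed, "kinetics")
    v_true = kcat * E0 * S / (K_M + S)  # uM/min per series
    conc = np.outer(t, v_true)
    if noise_sd > 0:
        conc = conc + rng.normal(0, noise_sd, conc.shape)
    absorbance = standard_curve_slope * conc + blank
    return KineticsDataset(
        t=t,
        substrate=S,
        conc=conc,
        E0=E0,
        absorbance=absorbance,
        standard_curve_slope=standard_curve_slope,
        blank=blank,
        ground_truth={"kcat": kcat, "K_M": K_M, "v_true": v_true},
    )
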