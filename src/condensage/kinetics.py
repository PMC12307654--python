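"""Enzyme kinetics and aggregation kinetics.

Covers the plate-reader side of the analysis: conversion of absorbance traces
to product concentration via a standard curve, initial-rate estimation from
the early linear regime, Michaelis-Menten fitting of rate-vs-substrate data
(kcat, K_M, catalytic efficiency), relative reaction rates against a
condensate-free control, and the sigmoid fit of thioflavin-T (ThT)
fluorescence that tracks beta-sheet accumulation during condensate aging:

    I(t) = I0 + (Imax - I0) / (1 + exp(-k (t - t_half))).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

__all__ = [
    "KineticsDataset",
    "ThTSeries",
    "MentenFit",
    "SigmoidFit",
    "absorbance_to_conc",
    "initial_rate",
    "fit_menten",
    "relative_rate",
    "fit_sigmoid",
]


@dataclass
class KineticsDataset:
    """Product-formation time courses at several substrate concentrations.

    ``conc`` holds one column per substrate level (uM product vs ``t`` in
    minutes); ``absorbance`` optionally holds the matching raw plate-reader
    signal related by ``conc = (A - blank) / standard_curve_slope``.
    """

    t: np.ndarray  # min
    substrate: np.ndarray  # uM, one entry per series
    conc: np.ndarray  # (n_times, n_series) uM
    E0: float  # uM enzyme
    absorbance: np.ndarray | None = None  # (n_times, n_series) a.u.
    standard_curve_slope: float = 0.01  # a.u. per uM
    blank: float = 0.0  # a.u.
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    def to_csv(self, path) -> None:
        cols = {"t_min": self.t}
        for s, col in zip(self.substrate, np.atleast_2d(self.conc.T)):
            cols[f"S_{s:g}_uM"] = col
        pd.DataFrame(cols).to_csv(path, index=False)


@dataclass
class ThTSeries:
    """A ThT fluorescence time course (hours, arbitrary units)."""

    t: np.ndarray  # h
    intensity: np.ndarray  # a.u.
    ground_truth: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_h": self.t, "intensity": self.intensity}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "ThTSeries":
        df = pd.read_csv(path)
        return cls(t=df["t_h"].to_numpy(), intensity=df["intensity"].to_numpy())


@dataclass
class MentenFit:
    """Michaelis-Menten parameters: v = Vmax * S / (K_M + S), kcat = Vmax/E0."""

    kcat: float  # 1/min
    K_M: float  # uM
    Vmax: float  # uM/min
    efficiency: float  # kcat/K_M, per uM*min
    rss: float
    identifiable: bool = True


@dataclass
class SigmoidFit:
    """Logistic aggregation-kinetics parameters."""

    I0: float
    Imax: float
    k: float  # 1/h
    t_half: float  # h
    r_squared: float


def absorbance_to_conc(
    trace: np.ndarray, slope: float, blank: float = 0.0
) -> np.ndarray:
    """Convert absorbance to concentration: conc = (A - blank) / slope [uM].

    Negative conversions (noise below blank) are floored at zero with a
    warning reporting how many points were clipped.
    """
    if not slope > 0:
        raise ValueError("standard-curve slope must be > 0")
    conc = (np.asarray(trace, dtype=float) - blank) / slope
    n_neg = int(np.count_nonzero(conc < 0))
    if n_neg:
        warnings.warn(f"floored {n_neg} negative concentrations at 0", stacklevel=2)
        conc = np.clip(conc, 0.0, None)
    return conc


def initial_rate(
    t: np.ndarray, conc: np.ndarray, window: float | int = 0.2
) -> float:
    """Initial reaction rate [uM/min]: OLS slope of the early linear regime.

    ``window`` is either a fraction of the points (default first 20%) or an
    explicit point count; at least 3 points are always used.
    """
    t = np.asarray(t, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if isinstance(window, float) and window <= 1:
        n = max(3, int(round(window * len(t))))
    else:
        n = int(window)
    if n < 3:
        raise ValueError("initial-rate window must contain >= 3 points")
    if n > len(t):
        raise ValueError("window larger than the trace")
    return float(linregress(t[:n], conc[:n]).slope)


def _menten(S: np.ndarray, Vmax: float, K_M: float) -> np.ndarray:
    return Vmax * S / (K_M + S)


def fit_menten(rates: np.ndarray, E0: float) -> MentenFit:
    """Fit v = Vmax*S/(K_M + S) to (S, v) pairs and derive kcat and kcat/K_M.

    ``rates`` is an (n, 2) array of substrate concentration [uM] and initial
    rate [uM/min].  Initial guesses: Vmax = max v, K_M = S at half-maximal v.
    A fitted K_M further than 100x outside the sampled substrate range is
    flagged unidentifiable.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.ndim != 2 or rates.shape[1] != 2 or rates.shape[0] < 4:
        raise ValueError("need >= 4 (S, v) pairs")
    if not E0 > 0:
        raise ValueError("E0 must be > 0")
    S, v = rates[:, 0], rates[:, 1]
    vmax0 = float(np.max(v))
    half_idx = int(np.argmin(np.abs(v - vmax0 / 2)))
    km0 = max(float(S[half_idx]), 1e-9)
    try:
        popt, _ = curve_fit(
            _menten, S, v, p0=[vmax0, km0], bounds=(0, np.inf), maxfev=10000
        )
    except RuntimeError as exc:
        raise RuntimeError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    Vmax, K_M = map(float, popt)
    rss = float(np.sum((v - _menten(S, *popt)) ** 2))
    identifiable = S.min() / 100 <= K_M <= S.max() * 100
    if not identifiable:
        warnings.warn(
            f"K_M = {K_M:.3g} uM lies far outside the sampled substrate range; "
            "parameters unidentifiable",
            stacklevel=2,
        )
    kcat = Vmax / E0
    return MentenFit(
        kcat=kcat,
        K_M=K_M,
        Vmax=Vmax,
        efficiency=kcat / K_M,
        rss=rss,
        identifiable=identifiable,
    )


def relative_rate(rate_condensate: float, rate_control: float) -> float:
    """Reaction rate normalized to the condensate-free control.

    Values > 1 mean enhancement by the condensate, 1 parity, < 1 impairment.
    """
    if not rate_control > 0:
        raise ValueError("control rate must be > 0")
    return rate_condensate / rate_control


def _sigmoid(t: np.ndarray, I0: float, Imax: float, k: float, t_half: float) -> np.ndarray:
    return I0 + (Imax - I0) / (1.0 + np.exp(-k * (t - t_half)))


def fit_sigmoid(series: ThTSeries) -> SigmoidFit:
    """Fit the logistic growth model to a ThT time course.

    Requires >= 8 points spanning both asymptotes; a monotone-decreasing
    series is rejected (the model describes beta-sheet growth).
    """
    t = np.asarray(series.t, dtype=float)
    y = np.asarray(series.intensity, dtype=float)
    if len(t) < 8:
        raise ValueError("need >= 8 points to fit the sigmoid")
    n3 = max(2, len(y) // 4)
    if np.mean(y[-n3:]) < np.mean(y[:n3]):
        raise ValueError("series decreases over time; growth sigmoid inapplicable")

    i0, imax = float(np.min(y)), float(np.max(y))
    mid = 0.5 * (i0 + imax)
    t_half0 = float(t[int(np.argmin(np.abs(y - mid)))])
    # slope at the midpoint of a logistic is k*(Imax-I0)/4
    dy = np.gradient(y, t)
    k0 = max(4.0 * float(np.max(dy)) / max(imax - i0, 1e-12), 1e-3)
    try:
        popt, _ = curve_fit(
            _sigmoid,
            t,
            y,
            p0=[i0, imax, k0, t_half0],
            bounds=([-np.inf, -np.inf, 1e-9, -np.inf], np.inf),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"sigmoid fit did not converge: {exc}") from exc
    resid = y - _sigmoid(t, *popt)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 0.0
    return SigmoidFit(
        I0=float(popt[0]),
        Imax=float(popt[1]),
        k=float(popt[2]),
        t_half=float(popt[3]),
        r_squared=r2,
    )
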