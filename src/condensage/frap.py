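"""Fluorescence recovery after photobleaching (FRAP) quantification.

The full stack: acquisition-bleach correction against a reference region,
0-1 normalization, immobile/mobile fractions, single-exponential recovery
fitting for the half-time tau_1/2, and the apparent diffusion coefficient
D_app = 0.22 * r**2 / tau_1/2 for a circular bleach spot of radius r.

Conventions
-----------
* The correction factor is C_f(t) = R_i / R(t), with R_i the pre-bleach mean
  of the reference trace; the corrected ROI is I_cor = C_f * I.
* I_i is the mean of all pre-bleach corrected frames; I_min is the corrected
  intensity at the first post-bleach frame.
* I_n(t) = (I_cor - I_min) / (I_i - I_min), so full recovery is 1.
* F_im = (I_i - I_inf) / (I_i - I_min) and F_m = 1 - F_im exactly.
* By default I_inf is the fitted recovery asymptote (robust to end-of-trace
  noise); ``i_inf="last"`` uses the literal final corrected frame instead.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FrapRecord",
    "FrapFit",
    "correct_and_normalize",
    "immobile_fraction",
    "fit_recovery",
    "apparent_diffusion",
    "immobile_ratio",
    "relative_immobile",
    "analyze_frap",
]

#: headroom for I_inf marginally above I_i from noise before clipping
I_INF_TOLERANCE = 0.02


@dataclass
class FrapRecord:
    """One bleach experiment: ROI and reference intensity traces.

    ``bleach_frame`` indexes the first post-bleach sample; frames before it
    are pre-bleach.  ``bleach_radius`` is the bleached-spot radius in um.
    """

    t: np.ndarray  # s
    roi: np.ndarray  # a.u.
    reference: np.ndarray  # a.u.
    bleach_frame: int
    bleach_radius: float  # um
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.roi = np.asarray(self.roi, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if not (len(self.t) == len(self.roi) == len(self.reference)):
            raise ValueError("t, roi and reference must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.bleach_frame < 1:
            raise ValueError("bleach_frame must be >= 1 (need a pre-bleach point)")
        if not self.bleach_radius > 0:
            raise ValueError("bleach_radius must be > 0")

    def to_csv(self, path) -> None:
        path = Path(path)
        pd.DataFrame({"t_s": self.t, "roi": self.roi, "reference": self.reference}).to_csv(
            path, index=False
        )
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {"bleach_frame": int(self.bleach_frame), "bleach_radius_um": self.bleach_radius}
            )
        )

    @classmethod
    def from_csv(cls, path) -> "FrapRecord":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            t=df["t_s"].to_numpy(),
            roi=df["roi"].to_numpy(),
            reference=df["reference"].to_numpy(),
            bleach_frame=int(meta["bleach_frame"]),
            bleach_radius=float(meta["bleach_radius_um"]),
        )


@dataclass
class FrapFit:
    """Derived FRAP quantities; populated progressively by the pipeline."""

    I_i: float
    I_min: float
    C_f: np.ndarray
    I_cor: np.ndarray
    I_n: np.ndarray
    t_post: np.ndarray  # s, re-zeroed at the bleach frame
    I_inf: float | None = None
    F_im: float | None = None
    F_m: float | None = None
    tau_half: float | None = None
    D_app: float | None = None
    rss: float | None = None


def correct_and_normalize(rec: FrapRecord) -> FrapFit:
    """Bleach-correct the ROI trace against the reference and normalize to 0-1."""
    if np.any(rec.reference <= 0):
        raise ValueError("reference trace must be strictly positive")
    pre = slice(0, rec.bleach_frame)
    R_i = float(np.mean(rec.reference[pre]))
    C_f = R_i / rec.reference
    I_cor = C_f * rec.roi
    I_i = float(np.mean(I_cor[pre]))
    I_min = float(I_cor[rec.bleach_frame])
    if np.isclose(I_i, I_min):
        raise ValueError("degenerate record: no bleach detected (I_i == I_min)")
    I_n = (I_cor - I_min) / (I_i - I_min)
    t_post = rec.t[rec.bleach_frame :] - rec.t[rec.bleach_frame]
    return FrapFit(I_i=I_i, I_min=I_min, C_f=C_f, I_cor=I_cor, I_n=I_n, t_post=t_post)


def immobile_fraction(I_i: float, I_min: float, I_inf: float) -> tuple[float, float]:
    """Immobile and mobile fractions from pre-bleach, bleach and plateau levels.

    F_im = (I_i - I_inf) / (I_i - I_min);  F_m = 1 - F_im.
    """
    if not I_i > I_min:
        raise ValueError("requires I_i > I_min")
    if I_inf < I_min:
        raise ValueError("I_inf below I_min is unphysical")
    if I_inf > I_i * (1 + I_INF_TOLERANCE):
        warnings.warn(
            "I_inf exceeds pre-bleach intensity beyond tolerance; clipping to I_i",
            stacklevel=2,
        )
        I_inf = I_i
    I_inf = min(I_inf, I_i)
    F_im = (I_i - I_inf) / (I_i - I_min)
    return F_im, 1.0 - F_im


def _recovery_model(t: np.ndarray, F_m: float, tau_half: float) -> np.ndarray:
    return F_m * (1.0 - np.exp(-(np.log(2.0)) * t / tau_half))


def fit_recovery(
    I_n: np.ndarray, t_post: np.ndarray
) -> tuple[float, float, float]:
    """Fit I_n(t) = F_m * (1 - 2**(-t/tau_half)) to the post-bleach trace.

    Returns (F_m, tau_half, rss).  A flat trace yields F_m ~ 0 with tau_half
    flagged unidentifiable (nan).
    """
    I_n = np.asarray(I_n, dtype=float)
    t_post = np.asarray(t_post, dtype=float)
    if len(t_post) < 5:
        raise ValueError("need >= 5 post-bleach points to fit the recovery")
    if len(I_n) != len(t_post):
        raise ValueError("I_n and t_post must have equal length")

    last = float(I_n[-1])
    if np.ptp(I_n) < 1e-12:  # all-flat trace: amplitude 0, timescale undefined
        warnings.warn("flat recovery trace: tau_half unidentifiable", stacklevel=2)
        return 0.0, float("nan"), 0.0

    guess_fm = min(max(last, 1e-3), 1.2)
    above = np.nonzero(I_n >= 0.5 * last)[0]
    guess_tau = float(t_post[above[0]]) if len(above) and t_post[above[0]] > 0 else (
        float(t_post[-1]) / 4 or 1.0
    )
    try:
        popt, _ = curve_fit(
            _recovery_model,
            t_post,
            I_n,
            p0=[guess_fm, guess_tau],
            bounds=([0.0, 1e-9], [1.2, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"recovery fit did not converge: {exc}") from exc
    F_m, tau_half = float(popt[0]), float(popt[1])
    rss = float(np.sum((I_n - _recovery_model(t_post, *popt)) ** 2))
    return F_m, tau_half, rss


def apparent_diffusion(r: float, tau_half: float) -> float:
    """Apparent diffusion coefficient D_app = 0.22 * r**2 / tau_half [um^2/s]."""
    if not r > 0:
        raise ValueError("bleach radius r must be > 0")
    if not tau_half > 0:
        raise ValueError("tau_half must be > 0")
    return 0.22 * r**2 / tau_half


def immobile_ratio(f_a: float, f_b: float) -> float:
    """Ratio of two immobile fractions (both % or both fractions), 1-decimal."""
    if not f_b > 0:
        raise ValueError("denominator immobile fraction must be > 0")
    mixed = (f_a <= 1.0) != (f_b <= 1.0)
    if mixed:
        raise ValueError("mixed scales: pass both values as fractions or both as %")
    return round(f_a / f_b, 1)


def relative_immobile(f_sample: float, f_control: float) -> float:
    """Immobile fraction normalized to a solid-aggregate control."""
    if not f_control > 0:
        raise ValueError("control immobile fraction must be > 0")
    ratio = f_sample / f_control
    if ratio > 1.05:
        warnings.warn(
            f"sample exceeds the solid control ({ratio:.2f} > 1.05)", stacklevel=2
        )
    return ratio


def analyze_frap(
    rec: FrapRecord, i_inf: Literal["fitted", "last"] = "fitted"
) -> FrapFit:
    """Run the complete pipeline on one record.

    ``i_inf`` selects the plateau estimate for the immobile fraction: the
    fitted recovery asymptote (default) or the literal last corrected frame.
    """
    fit = correct_and_normalize(rec)
    I_n_post = fit.I_n[rec.bleach_frame :]
    F_m_fit, tau_half, rss = fit_recovery(I_n_post, fit.t_post)
    if i_inf == "fitted":
        I_inf = fit.I_min + F_m_fit * (fit.I_i - fit.I_min)
    elif i_inf == "last":
        I_inf = float(fit.I_cor[-1])
    else:
        raise ValueError("i_inf must be 'fitted' or 'last'")
    F_im, F_m = immobile_fraction(fit.I_i, fit.I_min, I_inf)
    fit.I_inf = I_inf
    fit.F_im, fit.F_m = F_im, F_m
    fit.tau_half = tau_half
    fit.rss = rss
    if tau_half and np.isfinite(tau_half):
        fit.D_app = apparent_diffusion(rec.bleach_radius, tau_half)
    return fit
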