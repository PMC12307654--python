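"""Synthetic FRAP records with known mobile fraction and recovery half-time.

The ROI trace follows the single-exponential recovery model scaled by the
bleach depth, and both ROI and reference decay with the same single-exponential
acquisition-photobleaching rate — the regime in which reference-based
correction is exact, so the analysis stage can be validated to the noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._rng import child_rng
from ..frap import FrapRecord

__all__ = ["FrapGroundTruth", "simulate_frap"]


@dataclass(frozen=True)
class FrapGroundTruth:
    """Ground-truth parameters of a simulated bleach experiment."""

    F_m_true: float  # mobile fraction, 0-1
    tau_half_true: float  # s
    acquisition_bleach_rate: float = 0.0  # 1/s
    bleach_depth: float = 0.8  # fraction of ROI intensity removed by the pulse
    bleach_radius: float = 1.0  # um
    noise_sd: float = 0.0  # a.u. (traces are O(1))

    def __post_init__(self) -> None:
        if not 0 <= self.F_m_true <= 1:
            raise ValueError("F_m_true must be within [0, 1]")
        if not self.tau_half_true > 0:
            raise ValueError("tau_half_true must be > 0")
        if not 0 < self.bleach_depth <= 1:
            raise ValueError("bleach_depth must be in (0, 1]")
        if self.acquisition_bleach_rate < 0:
            raise ValueError("acquisition_bleach_rate must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_frap(
    truth: FrapGroundTruth,
    n_pre: int = 5,
    n_post: int = 60,
    dt: float = 1.0,
    seed: int = 0,
) -> FrapRecord:
    """Simulate one FRAP record (pre-bleach baseline, bleach, recovery).

    The noise-free corrected ROI is

        I(t') = I_i * [(1 - d) + d * F_m * (1 - 2**(-t'/tau_half))]

    for post-bleach time t' with bleach depth d, multiplied by
    exp(-acquisition_bleach_rate * t) in recorded (absolute) time; the
    reference trace is R_i * exp(-acquisition_bleach_rate * t).  Gaussian
    noise of sd ``truth.noise_sd`` is added to both traces.
    """
    if n_pre < 1:
        raise ValueError("n_pre must be >= 1")
    if n_post < 2:
        raise ValueError("n_post must be >= 2")
    rng = child_rng(seed, "frap")
    I_i, R_i = 1.0, 1.0
    n = n_pre + n_post
    t = np.arange(n) * dt
    t_post = t[n_pre:] - t[n_pre]

    roi = np.empty(n)
    roi[:n_pre] = I_i
    d = truth.bleach_depth
    recovery = truth.F_m_true * (
        1.0 - np.exp(-np.log(2.0) * t_post / truth.tau_half_true)
    )
    roi[n_pre:] = I_i * ((1.0 - d) + d * recovery)

    decay = np.exp(-truth.acquisition_bleach_rate * t)
    roi = roi * decay
    reference = R_i * decay
    if truth.noise_sd > 0:
        roi = roi + rng.normal(0, truth.noise_sd, n)
        reference = reference + rng.normal(0, truth.noise_sd, n)

    return FrapRecord(
        t=t,
        roi=roi,
        reference=reference,
        bleach_frame=n_pre,
        bleach_radius=truth.bleach_radius,
        ground_truth={"truth": truth},
    )
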