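"""Render trajectory ensembles into synthetic fluorescence video stacks.

Each particle becomes an integrated 2D Gaussian spot (PSF width ``psf_sigma``)
on a Poisson-distributed background whose shot noise sets the signal-to-noise
ratio: peak amplitude = snr * sqrt(background mean).  ``snr = inf`` renders a
noiseless stack on a constant background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import erf

from .._rng import child_rng
from .trajectories import SimulationConfig, TrajectoryEnsemble

__all__ = ["FrameStack", "render_frames"]

DEFAULT_BACKGROUND = 100.0  # counts; sd = 10 counts


@dataclass
class FrameStack:
    """Multi-page 16-bit image stack plus the acquisition metadata needed to
    convert detections back to physical units."""

    images: np.ndarray  # (n_frames, height, width) uint16
    pixel_size_um: float
    dt_s: float

    @property
    def n_frames(self) -> int:
        return self.images.shape[0]

    def to_tiff(self, path) -> None:
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.images)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps({"pixel_size_um": self.pixel_size_um, "dt_s": self.dt_s})
        )

    @classmethod
    def from_tiff(cls, path) -> "FrameStack":
        import tifffile

        path = Path(path)
        images = tifffile.imread(path)
        if images.ndim == 2:
            images = images[None]
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            images=images,
            pixel_size_um=float(meta["pixel_size_um"]),
            dt_s=float(meta["dt_s"]),
        )


def _integrated_gaussian_patch(
    x0: float, y0: float, sigma: float, xlo: int, xhi: int, ylo: int, yhi: int
) -> np.ndarray:
    """Gaussian integrated over unit pixels, peak-normalized to ~1."""
    xs = np.arange(xlo, xhi)
    ys = np.arange(ylo, yhi)
    s = sigma * np.sqrt(2.0)
    fx = 0.5 * (erf((xs + 0.5 - x0) / s) - erf((xs - 0.5 - x0) / s))
    fy = 0.5 * (erf((ys + 0.5 - y0) / s) - erf((ys - 0.5 - y0) / s))
    # peak pixel integral of a centered Gaussian, used to normalize peak to 1
    peak = (0.5 * (erf(0.5 / s) - erf(-0.5 / s))) ** 2
    return np.outer(fy, fx) / peak


def render_frames(
    traj: TrajectoryEnsemble,
    psf_sigma: float,
    snr: float,
    config: SimulationConfig,
    shape: tuple[int, int] = (64, 64),
    background: float = DEFAULT_BACKGROUND,
    offset_um: tuple[float, float] | None = None,
    n_frames: int | None = None,
) -> FrameStack:
    """Render one image per frame of ``traj``.

    Parameters
    ----------
    psf_sigma : PSF standard deviation in um.
    snr : peak signal over background standard deviation; ``inf`` disables noise.
    shape : (height, width) of the field in pixels.
    offset_um : optional (x, y) shift applied to all positions before the
        um -> pixel conversion (the simulators start trajectories at the
        origin, so an offset is usually needed to center them in the field).
    """
    if not psf_sigma > 0:
        raise ValueError("psf_sigma must be > 0")
    if not snr > 0:
        raise ValueError("snr must be > 0")
    height, width = shape
    df = traj.data
    x = df["x_um"].to_numpy(copy=True)
    y = df["y_um"].to_numpy(copy=True)
    if offset_um is not None:
        x = x + offset_um[0]
        y = y + offset_um[1]
    xp = x / config.pixel_size
    yp = y / config.pixel_size

    outside = (xp < 0) | (xp >= width) | (yp < 0) | (yp >= height)
    if outside.any():
        bad = df.loc[outside, ["particle", "frame"]].head(5)
        raise ValueError(
            "particles outside the field of view (particle, frame): "
            + ", ".join(f"({int(p)}, {int(f)})" for p, f in bad.to_numpy())
        )

    sigma_px = psf_sigma / config.pixel_size
    noiseless = not np.isfinite(snr)
    amplitude = 1000.0 if noiseless else snr * np.sqrt(background)
    if n_frames is None:
        if not len(df):
            raise ValueError("empty ensemble: pass n_frames for a background-only stack")
        n_frames = int(df["frame"].max()) + 1
    stack = np.full((n_frames, height, width), background, dtype=float)

    half = int(np.ceil(4 * sigma_px))
    frames = df["frame"].to_numpy()
    for xi, yi, fi in zip(xp, yp, frames):
        cx, cy = int(round(xi)), int(round(yi))
        xlo, xhi = max(0, cx - half), min(width, cx + half + 1)
        ylo, yhi = max(0, cy - half), min(height, cy + half + 1)
        patch = _integrated_gaussian_patch(xi, yi, sigma_px, xlo, xhi, ylo, yhi)
        stack[int(fi), ylo:yhi, xlo:xhi] += amplitude * patch

    if not noiseless:
        rng = child_rng(config.seed, "frames")
        # Poisson shot noise on background counts only (spots added on top)
        noise = rng.poisson(background, size=stack.shape) - background
        stack = stack + noise

    stack = np.clip(np.round(stack), 0, 65535).astype(np.uint16)
    return FrameStack(images=stack, pixel_size_um=config.pixel_size, dt_s=config.dt)
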