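"""Probe-particle detection and trajectory linking from fluorescence video.

Crocker-Grier-style pipeline: per frame, a difference-of-Gaussians band-pass
(at sigma and 3*sigma) suppresses background and noise, local maxima above a
threshold are refined to sub-pixel positions by intensity-weighted centroids,
and detections are linked frame-to-frame by minimum-total-squared-displacement
assignment (Hungarian algorithm) gated at a maximum displacement, with
short-gap memory and a minimum track length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max

from .synthetic.frames import FrameStack
from .synthetic.trajectories import TrajectoryEnsemble

__all__ = ["Localization", "LinkingParams", "detect_spots", "link_trajectories"]

log = logging.getLogger(__name__)

_INFEASIBLE = 1e12


@dataclass(frozen=True)
class Localization:
    """One sub-pixel detection."""

    frame: int
    x: float  # pixels, sub-pixel
    y: float  # pixels
    intensity: float  # integrated band-passed intensity, a.u.


@dataclass(frozen=True)
class LinkingParams:
    """Gates for frame-to-frame assignment."""

    max_displacement: float  # pixels
    memory: int = 0  # frames a particle may vanish and still be re-linked
    min_track_length: int = 2  # localizations; shorter tracks are dropped

    def __post_init__(self) -> None:
        if not self.max_displacement > 0:
            raise ValueError("max_displacement must be > 0")
        if self.memory < 0:
            raise ValueError("memory must be >= 0")
        if self.min_track_length < 2:
            raise ValueError("min_track_length must be >= 2")


def detect_spots(
    stack: FrameStack, spot_sigma: float, threshold_sd: float = 5.0
) -> list[Localization]:
    """Detect fluorescent spots in every frame of ``stack``.

    Candidate maxima on the band-passed frame must exceed its background mean
    plus ``threshold_sd`` standard deviations; each is refined by an
    intensity-weighted centroid in a (2*ceil(3*sigma)+1)^2 window.  Spots whose
    refinement window exits the frame are discarded to avoid edge bias.
    """
    if not spot_sigma > 0:
        raise ValueError("spot_sigma must be > 0")
    if stack.images.size == 0 or stack.n_frames == 0:
        raise ValueError("empty frame stack")

    half = int(np.ceil(3 * spot_sigma))
    locs: list[Localization] = []
    for fi, frame in enumerate(stack.images):
        img = frame.astype(float)
        if np.issubdtype(stack.images.dtype, np.integer):
            sat = np.iinfo(stack.images.dtype).max
            if (frame == sat).any():
                log.warning("frame %d contains saturated pixels", fi)
        bandpass = gaussian_filter(img, spot_sigma) - gaussian_filter(
            img, 3 * spot_sigma
        )
        bg_mean = float(np.mean(bandpass))
        bg_sd = float(np.std(bandpass))
        threshold = bg_mean + threshold_sd * bg_sd
        peaks = peak_local_max(
            bandpass,
            min_distance=max(1, int(np.ceil(2 * spot_sigma))),
            threshold_abs=threshold,
            exclude_border=False,
        )
        h, w = bandpass.shape
        for py, px in peaks:
            if not (half <= px < w - half and half <= py < h - half):
                continue  # refinement window would exit the frame
            window = bandpass[py - half : py + half + 1, px - half : px + half + 1]
            weights = np.clip(window - bg_mean, 0, None)
            total = weights.sum()
            if total <= 0:
                continue
            ys, xs = np.mgrid[-half : half + 1, -half : half + 1]
            locs.append(
                Localization(
                    frame=fi,
                    x=px + float((weights * xs).sum() / total),
                    y=py + float((weights * ys).sum() / total),
                    intensity=float(total),
                )
            )
    return locs


class _Track:
    __slots__ = ("points", "last_frame", "last_pos")

    def __init__(self, frame: int, x: float, y: float) -> None:
        self.points: list[tuple[int, float, float]] = [(frame, x, y)]
        self.last_frame = frame
        self.last_pos = (x, y)

    def append(self, frame: int, x: float, y: float) -> None:
        self.points.append((frame, x, y))
        self.last_frame = frame
        self.last_pos = (x, y)


def link_trajectories(
    locs: list[Localization],
    params: LinkingParams,
    pixel_size: float,
    dt: float,
) -> TrajectoryEnsemble:
    """Link localizations into trajectories and convert to um and seconds.

    Frame-to-frame assignment minimizes the total squared displacement over
    all candidate pairs within ``max_displacement`` (Hungarian algorithm on
    the gated cost matrix; ties resolved deterministically by track index).
    Tracks absent for at most ``memory`` frames are re-linked at their last
    position; tracks with fewer than ``min_track_length`` points are dropped.
    """
    if not pixel_size > 0 or not dt > 0:
        raise ValueError("pixel_size and dt must be > 0")
    if any(l.frame < 0 for l in locs):
        raise ValueError("negative frame index in localizations")

    by_frame: dict[int, list[Localization]] = {}
    for l in locs:
        by_frame.setdefault(l.frame, []).append(l)

    max_sq = params.max_displacement**2
    tracks: list[_Track] = []
    active: list[_Track] = []
    for frame in sorted(by_frame):
        dets = by_frame[frame]
        # retire tracks that have been dark longer than the memory allows
        active = [t for t in active if frame - t.last_frame - 1 <= params.memory]
        assigned_det = set()
        if active and dets:
            cost = np.full((len(active), len(dets)), _INFEASIBLE)
            for i, tr in enumerate(active):
                tx, ty = tr.last_pos
                for j, d in enumerate(dets):
                    sq = (d.x - tx) ** 2 + (d.y - ty) ** 2
                    if sq <= max_sq:
                        cost[i, j] = sq
            rows, cols = linear_sum_assignment(cost)
            matched_tracks = set()
            for i, j in zip(rows, cols):
                if cost[i, j] < _INFEASIBLE:
                    active[i].append(frame, dets[j].x, dets[j].y)
                    assigned_det.add(j)
                    matched_tracks.add(i)
        for j, d in enumerate(dets):
            if j not in assigned_det:
                t = _Track(frame, d.x, d.y)
                tracks.append(t)
                active.append(t)

    rows = []
    pid = 0
    for t in tracks:
        if len(t.points) < params.min_track_length:
            continue
        for frame, x, y in t.points:
            rows.append((pid, frame, frame * dt, x * pixel_size, y * pixel_size))
        pid += 1
    df = pd.DataFrame(rows, columns=["particle", "frame", "t_s", "x_um", "y_um"])
    return TrajectoryEnsemble(data=df, dt=dt)
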