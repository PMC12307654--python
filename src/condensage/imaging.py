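"""Condensate-level image metrics.

Segmentation of condensates from the scaffold channel, the cargo enrichment
index (mean client fluorescence inside vs. outside the condensates), relative
condensate counts for dissolution assays (1,6-hexanediol, dilution), and
two-channel line profiles for colocalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from scipy.stats import pearsonr
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import profile_line, regionprops
from skimage.morphology import disk

__all__ = [
    "CondensateImage",
    "SegmentationResult",
    "segment_condensates",
    "enrichment_index",
    "relative_count",
    "line_profile",
]


@dataclass
class CondensateImage:
    """Two-channel field: phase-forming scaffold and recruited cargo."""

    scaffold_channel: np.ndarray
    cargo_channel: np.ndarray
    pixel_size: float = 0.1  # um/px
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scaffold_channel = np.asarray(self.scaffold_channel, dtype=float)
        self.cargo_channel = np.asarray(self.cargo_channel, dtype=float)
        if self.scaffold_channel.shape != self.cargo_channel.shape:
            raise ValueError("channels must share dimensions")
        if np.any(self.scaffold_channel < 0) or np.any(self.cargo_channel < 0):
            raise ValueError("intensities must be non-negative")

    def to_tiff(self, path) -> None:
        import tifffile

        stacked = np.stack([self.scaffold_channel, self.cargo_channel]).astype(
            np.float32
        )
        tifffile.imwrite(path, stacked)

    @classmethod
    def from_tiff(cls, path, pixel_size: float = 0.1) -> "CondensateImage":
        import tifffile

        stacked = tifffile.imread(path)
        if stacked.ndim != 3 or stacked.shape[0] != 2:
            raise ValueError("expected a 2-channel (2, H, W) TIFF")
        return cls(
            scaffold_channel=stacked[0],
            cargo_channel=stacked[1],
            pixel_size=pixel_size,
        )


@dataclass
class SegmentationResult:
    """Labelled condensates (0 = background) with per-label statistics."""

    label_map: np.ndarray
    n_condensates: int
    stats: pd.DataFrame  # label, area_px, centroid_y, centroid_x, per-channel means


def segment_condensates(
    img: CondensateImage,
    threshold_mode: str = "otsu",
    min_area_px: int = 9,
    fixed_threshold: float | None = None,
) -> SegmentationResult:
    """Threshold the scaffold channel and label connected condensates.

    Otsu thresholding by default (invariant under global intensity scaling);
    ``threshold_mode="fixed"`` uses ``fixed_threshold`` instead.  Components
    smaller than ``min_area_px`` are removed as shot noise.
    """
    scaffold = img.scaffold_channel
    if scaffold.size == 0:
        raise ValueError("empty image")
    if threshold_mode == "otsu":
        if np.ptp(scaffold) == 0:  # flat image: nothing to segment
            mask = np.zeros_like(scaffold, dtype=bool)
        else:
            mask = scaffold > threshold_otsu(scaffold)
            # Otsu bisects pure noise when no condensates are present; require
            # real contrast between the two classes before accepting the mask
            if mask.any() and not mask.all():
                fg, bg = scaffold[mask], scaffold[~mask]
                if fg.mean() - bg.mean() < 4.0 * bg.std():
                    mask = np.zeros_like(scaffold, dtype=bool)
    elif threshold_mode == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed mode requires fixed_threshold")
        mask = scaffold > fixed_threshold
    else:
        raise ValueError("threshold_mode must be 'otsu' or 'fixed'")

    labels = sk_label(mask, connectivity=2)
    rows = []
    keep = np.zeros_like(labels)
    next_id = 0
    for prop in regionprops(labels):
        if prop.area < min_area_px:
            continue
        next_id += 1
        keep[labels == prop.label] = next_id
        coords = prop.coords
        rows.append(
            {
                "label": next_id,
                "area_px": int(prop.area),
                "centroid_y": prop.centroid[0],
                "centroid_x": prop.centroid[1],
                "mean_scaffold": float(scaffold[coords[:, 0], coords[:, 1]].mean()),
                "mean_cargo": float(
                    img.cargo_channel[coords[:, 0], coords[:, 1]].mean()
                ),
            }
        )
    stats = pd.DataFrame(
        rows,
        columns=[
            "label",
            "area_px",
            "centroid_y",
            "centroid_x",
            "mean_scaffold",
            "mean_cargo",
        ],
    )
    return SegmentationResult(label_map=keep, n_condensates=next_id, stats=stats)


def enrichment_index(
    img: CondensateImage,
    seg: SegmentationResult,
    per_condensate: bool = False,
    halo_px: int = 2,
) -> float:
    """Cargo enrichment: mean cargo intensity inside condensates over mean
    cargo intensity in the background.

    Background excludes a ``halo_px``-dilated rim around every condensate to
    avoid edge-blur bias.  By default all condensate pixels are pooled;
    ``per_condensate=True`` averages one index per condensate instead.
    """
    if seg.n_condensates < 1:
        raise ValueError("need at least one condensate")
    inside = seg.label_map > 0
    background = ~binary_dilation(inside, structure=disk(halo_px))
    if not background.any():
        raise ValueError("no background pixels outside the dilated condensates")
    bg_mean = float(img.cargo_channel[background].mean())
    if bg_mean == 0:
        raise ValueError("zero background mean; enrichment undefined")
    if per_condensate:
        indices = [
            float(img.cargo_channel[seg.label_map == lbl].mean()) / bg_mean
            for lbl in range(1, seg.n_condensates + 1)
        ]
        return float(np.mean(indices))
    return float(img.cargo_channel[inside].mean()) / bg_mean


def relative_count(before: SegmentationResult, after: SegmentationResult) -> float:
    """Condensate count after treatment as a percentage of the count before."""
    if before.n_condensates <= 0:
        raise ValueError("before-treatment count must be > 0")
    return 100.0 * after.n_condensates / before.n_condensates


def line_profile(
    img: CondensateImage,
    p0: tuple[float, float],
    p1: tuple[float, float],
    width_px: int = 1,
) -> dict:
    """Two-channel normalized intensity profile along a segment.

    Points are (row, col) pixel coordinates.  Each channel is sampled by
    bilinear interpolation averaged over ``width_px`` perpendicular lines and
    min-max normalized to [0, 1]; the Pearson correlation between the two
    profiles is reported.  A constant channel degenerates: its profile is
    returned as all zeros with ``degenerate=True`` and correlation nan.
    """
    h, w = img.scaffold_channel.shape
    for p in (p0, p1):
        if not (0 <= p[0] <= h - 1 and 0 <= p[1] <= w - 1):
            raise ValueError(f"endpoint {p} outside image")
    if np.allclose(p0, p1):
        raise ValueError("zero-length segment")

    profiles = {}
    degenerate = False
    for name, channel in (
        ("scaffold", img.scaffold_channel),
        ("cargo", img.cargo_channel),
    ):
        raw = profile_line(
            channel, p0, p1, linewidth=width_px, order=1, mode="reflect"
        )
        span = np.ptp(raw)
        if span == 0:
            warnings.warn(f"{name} profile is constant; normalization degenerate",
                          stacklevel=2)
            profiles[name] = np.zeros_like(raw)
            degenerate = True
        else:
            profiles[name] = (raw - raw.min()) / span

    distance = np.arange(len(profiles["scaffold"])) * img.pixel_size
    if degenerate:
        corr = float("nan")
    elif np.allclose(profiles["scaffold"], profiles["cargo"]):
        corr = 1.0
    else:
        corr = float(pearsonr(profiles["scaffold"], profiles["cargo"])[0])
    return {
        "distance_um": distance,
        "scaffold": profiles["scaffold"],
        "cargo": profiles["cargo"],
        "pearson_r": corr,
        "degenerate": degenerate,
    }
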