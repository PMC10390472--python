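"""Spheroid section quantification: staining profiles, contrast, invasion.

Covers the section-level measurements used to compare staining the intact
3D sample against re-staining cryosections: bisecting-line intensity
profiles normalized to their own maximum, per-slice averages, maximum-based
signal-to-background ratios, and the invasive-distance metric — the
circumference of a circle enclosing at least 90% of the invasive front at
t = 48 h minus the circumference of the circle fully enclosing the core at
t = 1 h.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .core import PixelImage
from .stats import compare_groups, significance_stars  # noqa: F401  (shared stats engine)

__all__ = [
    "IntensityProfile",
    "InvasionMeasurement",
    "SBRatio",
    "bisecting_profile",
    "per_slice_summary",
    "signal_to_background",
    "segment_core",
    "front_radius",
    "invasive_distance",
    "compare_groups",
    "plot_slice_boxes",
]


@dataclass
class IntensityProfile:
    """Intensity samples along a line bisecting the spheroid."""

    positions_um: np.ndarray
    raw: np.ndarray
    normalized: np.ndarray
    slice_index: int = 0
    channel: str = ""
    flagged: bool = False  # True when the raw maximum was zero

    def __post_init__(self) -> None:
        if self.positions_um.size < 2:
            raise ValueError("profile needs at least 2 samples")


@dataclass
class InvasionMeasurement:
    """Invasive distance as a difference of enclosing-circle circumferences."""

    r_core_um: float
    r_front_um: float
    n_invasive: int
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.r_core_um < 0 or self.r_front_um < 0:
            raise ValueError("radii must be non-negative")

    @property
    def invasive_distance_um(self) -> float:
        return 2.0 * np.pi * (self.r_front_um - self.r_core_um)


@dataclass
class SBRatio:
    """Max intensity inside signal ROIs over max intensity in background ROIs."""

    channel: str
    signal_max: float
    background_max: float

    @property
    def ratio(self) -> float:
        return self.signal_max / self.background_max


def _channel_data(image: PixelImage, channel: str | int | None) -> np.ndarray:
    data = image.data
    if data.ndim == 2:
        return data.astype(float)
    channels = image.meta.get("channels")
    if isinstance(channel, str):
        if not channels or channel not in channels:
            raise ValueError(f"channel {channel!r} not found in image metadata")
        return data[channels.index(channel)].astype(float)
    if channel is None:
        raise ValueError("multichannel image requires a channel selection")
    return data[int(channel)].astype(float)


def bisecting_profile(
    image: PixelImage,
    center_um: tuple[float, float],
    angle_deg: float = 0.0,
    channel: str | int | None = None,
    slice_index: int = 0,
) -> IntensityProfile:
    """Edge-to-edge intensity profile through the spheroid centre.

    The line runs through ``center_um`` at ``angle_deg`` (0° = horizontal),
    sampled at the pixel size; intensities are normalized to the maximum
    along the line. An all-zero line skips normalization and is flagged.
    """
    data = _channel_data(image, channel)
    ps = image.pixel_size_um
    h, w = data.shape[0] * ps, data.shape[1] * ps
    cx, cy = center_um
    if not (0 <= cx <= w and 0 <= cy <= h):
        raise ValueError("profile centre outside the image")
    dx, dy = np.cos(np.radians(angle_deg)), np.sin(np.radians(angle_deg))
    # clip the infinite line to the field
    ts = []
    for d, c, lim in ((dx, cx, w), (dy, cy, h)):
        if abs(d) > 1e-12:
            ts.extend([(0 - c) / d, (lim - c) / d])
    t0, t1 = max(t for t in ts if t <= 0), min(t for t in ts if t >= 0)
    n = max(int(np.ceil((t1 - t0) / ps)) + 1, 2)
    t = np.linspace(t0, t1, n)
    x, y = cx + t * dx, cy + t * dy
    coords = np.vstack([np.clip(y / ps - 0.5, 0, data.shape[0] - 1), np.clip(x / ps - 0.5, 0, data.shape[1] - 1)])
    raw = ndimage.map_coordinates(data, coords, order=1, mode="nearest")
    peak = float(raw.max())
    flagged = peak <= 0
    normalized = raw.copy() if flagged else raw / peak
    ch_name = channel if isinstance(channel, str) else str(channel or "")
    return IntensityProfile(t - t0, raw, normalized, slice_index, ch_name, flagged)


def per_slice_summary(profiles: Sequence[IntensityProfile]) -> pd.DataFrame:
    """Per-slice distribution of normalized intensities, for box-whisker plots."""
    if not profiles:
        raise ValueError("need at least one profile")
    rows = []
    for s in sorted({p.slice_index for p in profiles}):
        vals = np.concatenate([p.normalized for p in profiles if p.slice_index == s])
        rows.append(
            {
                "slice": s,
                "mean": float(vals.mean()),
                "median": float(np.median(vals)),
                "q1": float(np.percentile(vals, 25)),
                "q3": float(np.percentile(vals, 75)),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "n": int(vals.size),
            }
        )
    return pd.DataFrame(rows)


def plot_slice_boxes(profiles: Sequence[IntensityProfile], path: str) -> None:
    """Box-and-whisker plot of normalized intensity per slice, saved to file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    slices = sorted({p.slice_index for p in profiles})
    data = [
        np.concatenate([p.normalized for p in profiles if p.slice_index == s]) for s in slices
    ]
    fig, ax = plt.subplots(figsize=(1.2 * max(len(slices), 3), 4))
    ax.boxplot(data, tick_labels=[str(s) for s in slices])
    ax.set_xlabel("slice")
    ax.set_ylabel("normalized intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _roi_max(data: np.ndarray, rois: Sequence, pixel_size_um: float) -> float:
    """Max intensity over a set of ROIs (boolean masks or (x0, y0, x1, y1) μm rects)."""
    best = -np.inf
    for roi in rois:
        if isinstance(roi, np.ndarray) and roi.dtype == bool:
            vals = data[roi]
        else:
            x0, y0, x1, y1 = roi
            i0, i1 = int(y0 / pixel_size_um), int(np.ceil(y1 / pixel_size_um))
            j0, j1 = int(x0 / pixel_size_um), int(np.ceil(x1 / pixel_size_um))
            vals = data[i0:i1, j0:j1]
        if vals.size:
            best = max(best, float(vals.max()))
    if not np.isfinite(best):
        raise ValueError("ROI set selects no pixels")
    return best


def signal_to_background(
    image: PixelImage,
    signal_rois: Sequence,
    background_rois: Sequence,
    channel: str | int | None = None,
) -> SBRatio:
    """Ratio of the maximum intensity over cell ROIs to the maximum outside."""
    if not signal_rois or not background_rois:
        raise ValueError("signal and background ROI sets must be non-empty")
    data = _channel_data(image, channel)
    sig = _roi_max(data, signal_rois, image.pixel_size_um)
    bg = _roi_max(data, background_rois, image.pixel_size_um)
    if bg <= 0:
        raise ValueError("background maximum is zero; ratio undefined")
    ch_name = channel if isinstance(channel, str) else str(channel or "")
    return SBRatio(ch_name, sig, bg)


def segment_core(
    image: PixelImage, channel: str | int | None = None, polarity: str = "bright"
) -> tuple[np.ndarray, tuple[float, float], float]:
    """Otsu + largest connected component + hole filling.

    Returns ``(mask, centroid_um (x, y), r_core_um)`` where the core radius
    is the distance from the centroid to the farthest mask pixel — the
    radius of the smallest centred circle fully enclosing the core.
    """
    data = _channel_data(image, channel)
    if polarity == "dark":
        data = data.max() - data
    mask = data > threshold_otsu(data)
    labels = label(mask)
    if labels.max() == 0:
        raise ValueError("no foreground found when segmenting the core")
    largest = max(regionprops(labels), key=lambda r: r.area)
    core = ndimage.binary_fill_holes(labels == largest.label)
    ps = image.pixel_size_um
    ys, xs = np.nonzero(core)
    cy, cx = ys.mean(), xs.mean()
    r_core = float(np.hypot(ys - cy, xs - cx).max() * ps)
    return core, ((cx + 0.5) * ps, (cy + 0.5) * ps), r_core


def front_radius(radii_um: np.ndarray, fraction: float = 0.9) -> float:
    """Radius of the smallest centred circle enclosing at least ``fraction`` of the points.

    The exact order statistic: with n points, the sorted radius at index
    ceil(fraction·n) − 1, so the circle always encloses >= fraction of the
    cells (an interpolated quantile can fall just short for some n).
    """
    radii = np.sort(np.asarray(radii_um, dtype=float))
    if radii.size == 0:
        raise ValueError("no invasive cells")
    k = int(np.ceil(fraction * radii.size)) - 1
    return float(radii[max(k, 0)])


def invasive_distance(
    image_t1h: PixelImage,
    image_t48h: PixelImage,
    channel: str | int | None = None,
    polarity: str = "bright",
    min_cell_area_px: int = 4,
    fraction: float = 0.9,
) -> InvasionMeasurement:
    """Invasive distance between a 1 h core image and a 48 h invasion image.

    The core circle is centred on the t = 1 h core centroid and fully
    encloses the core mask; the front circle (same centre) encloses at
    least 90% of the invading-cell centroids segmented outside the core at
    t = 48 h. The metric is the difference of the two circumferences. With
    no invasive cells the result is zero and flagged.
    """
    _, (cx, cy), r_core = segment_core(image_t1h, channel, polarity)
    data = _channel_data(image_t48h, channel)
    if polarity == "dark":
        data = data.max() - data
    mask = data > threshold_otsu(data)
    labels = label(mask)
    ps = image_t48h.pixel_size_um
    radii = []
    for region in regionprops(labels):
        if region.area < min_cell_area_px:
            continue
        ry, rx = region.centroid
        r = float(np.hypot((rx + 0.5) * ps - cx, (ry + 0.5) * ps - cy))
        if r > r_core:
            radii.append(r)
    if not radii:
        return InvasionMeasurement(r_core, r_core, 0, flagged=True)
    r_front = max(front_radius(np.asarray(radii), fraction), r_core)
    return InvasionMeasurement(r_core, r_front, len(radii))
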