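"""Characteristic pore size of fibrillar networks from inter-fiber gaps.

The estimator mirrors the uniform workflow applied to every imaging
context: band-pass filtering plus rolling-ball background subtraction,
auto local thresholding to a binary fiber mask, row-by-row and
column-by-column counting of the off-pixel gaps between "on" pixels, and a
fit of the pooled gap-length sample to the exponential probability density
f(x) = λ·exp(−λx). The reported pore size is the characteristic length
1/λ. Border-truncated gaps are censored observations and are excluded by
default (including them biases λ̂ low).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.stats import kstest
from skimage.filters import threshold_niblack, threshold_otsu, threshold_sauvola
from skimage.restoration import rolling_ball

from .core import PixelImage

__all__ = [
    "BinarizedNetwork",
    "PoreSizeResult",
    "PoreConfig",
    "preprocess",
    "binarize",
    "count_gaps",
    "fit_exponential",
    "pore_size_pipeline",
]


@dataclass
class BinarizedNetwork:
    """Boolean fiber mask (True = fiber) with pixel size and provenance."""

    mask: np.ndarray
    pixel_size_um: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any() or self.mask.all():
            raise ValueError("binarized image must contain both on and off pixels")


@dataclass
class PoreSizeResult:
    """Gap sample, fitted exponential rate, and characteristic pore size 1/λ."""

    gaps_um: np.ndarray
    rate_per_um: float
    n_gaps: int
    ks_statistic: float
    ks_pvalue: float

    @property
    def pore_size_um(self) -> float:
        return 1.0 / self.rate_per_um


@dataclass(frozen=True)
class PoreConfig:
    """One processing configuration, applied identically to every image in a batch.

    The filter scales and threshold window are workflow defaults, not
    measured constants; they are deliberately shared across imaging
    contexts to avoid differential bias.
    """

    bandpass_small_px: float = 2.0
    bandpass_large_px: float = 40.0
    rollingball_radius_px: float = 50.0
    threshold_method: str = "phansalkar"
    window_px: int = 15
    min_gaps: int = 100
    fit_method: str = "mle"
    include_border_gaps: bool = False
    pool_images: bool = True


def preprocess(
    image: PixelImage,
    bandpass_small_px: float = 2.0,
    bandpass_large_px: float = 40.0,
    rollingball_radius_px: float = 50.0,
) -> PixelImage:
    """Difference-of-Gaussians band-pass then rolling-ball background removal.

    The band-pass suppresses features below the small scale (single-pixel
    noise) and above the large scale (out-of-plane haze); the rolling ball
    removes any remaining smooth background. Output is clipped to be
    non-negative.
    """
    data = image.data.astype(float)
    if not 0 < bandpass_small_px < bandpass_large_px < min(data.shape):
        raise ValueError("require 0 < small < large < min(image dims)")
    band = ndimage.gaussian_filter(data, bandpass_small_px) - ndimage.gaussian_filter(
        data, bandpass_large_px
    )
    band -= band.min()
    # large-radius rolling ball on a downscaled copy (standard speedup: the
    # background is smooth at the ball scale, so coarse estimation is exact
    # to interpolation error)
    shrink = max(1, int(rollingball_radius_px // 10))
    if shrink > 1:
        coarse = band[::shrink, ::shrink]
        bg_coarse = rolling_ball(coarse, radius=rollingball_radius_px / shrink)
        background = ndimage.zoom(bg_coarse, np.array(band.shape) / np.array(bg_coarse.shape), order=1)
    else:
        background = rolling_ball(band, radius=rollingball_radius_px)
    out = np.clip(band - background, 0.0, None)
    return image.with_data(out)


def _threshold_phansalkar(
    data: np.ndarray, window_px: int, k: float = 0.25, r: float = 0.5, p: float = 2.0, q: float = 10.0
) -> np.ndarray:
    """Phansalkar local threshold for low-contrast images.

    t = m·(1 + p·exp(−q·m) + k·(s/R − 1)) on the image normalized to [0, 1],
    with m and s the local mean and standard deviation.
    """
    lo, hi = float(data.min()), float(data.max())
    norm = (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)
    mean = ndimage.uniform_filter(norm, window_px)
    sq = ndimage.uniform_filter(norm**2, window_px)
    std = np.sqrt(np.clip(sq - mean**2, 0.0, None))
    thresh = mean * (1.0 + p * np.exp(-q * mean) + k * (std / r - 1.0))
    return norm > thresh


def binarize(
    image: PixelImage,
    method: str = "phansalkar",
    window_px: int = 15,
    polarity: str = "bright",
) -> BinarizedNetwork:
    """Auto local threshold producing the on/off fiber mask.

    ``method`` is one of phansalkar (default), sauvola, niblack, otsu;
    ``polarity="dark"`` inverts the image first so dark fibers on a bright
    background yield the same mask as the bright-fiber case.
    """
    data = image.data.astype(float)
    if polarity == "dark":
        data = data.max() - data
    elif polarity != "bright":
        raise ValueError(f"unknown polarity {polarity!r}")
    win = window_px if window_px % 2 == 1 else window_px + 1
    if method == "phansalkar":
        mask = _threshold_phansalkar(data, win)
    elif method == "sauvola":
        mask = data > threshold_sauvola(data, window_size=win)
    elif method == "niblack":
        mask = data > threshold_niblack(data, window_size=win)
    elif method == "otsu":
        mask = data > threshold_otsu(data)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return BinarizedNetwork(
        mask,
        image.pixel_size_um,
        provenance={"method": method, "window_px": win, "polarity": polarity},
    )


def _line_gaps(line: np.ndarray, include_border: bool) -> np.ndarray:
    """Lengths (px) of maximal off-runs; interior runs only unless requested."""
    idx = np.flatnonzero(line)
    if idx.size == 0:
        return np.empty(0, dtype=int)
    gaps = np.diff(idx) - 1
    gaps = gaps[gaps > 0]
    if include_border:
        border = [g for g in (idx[0], line.size - 1 - idx[-1]) if g > 0]
        gaps = np.concatenate([gaps, np.asarray(border, dtype=int)])
    return gaps


def count_gaps(network: BinarizedNetwork, include_border: bool = False) -> np.ndarray:
    """Measure off-pixel gaps between on pixels, row by row and column by column.

    Each maximal run of off pixels strictly between two on pixels
    contributes its length × pixel size (μm) to the sample; rows and
    columns are pooled. Border-truncated runs are censored and excluded by
    default.
    """
    mask = network.mask
    samples = []
    for row in mask:
        samples.append(_line_gaps(row, include_border))
    for col in mask.T:
        samples.append(_line_gaps(col, include_border))
    gaps_px = np.concatenate(samples) if samples else np.empty(0, dtype=int)
    if gaps_px.size == 0:
        raise ValueError("no interior gaps found in the mask")
    return gaps_px.astype(float) * network.pixel_size_um


def fit_exponential(
    gaps_um: np.ndarray,
    min_gaps: int = 100,
    method: str = "mle",
    n_hist_bins: int = 50,
) -> PoreSizeResult:
    """Fit the gap sample to f(x) = λ·exp(−λx) and report pore size 1/λ.

    ``mle`` (default) uses the closed form λ̂ = 1/mean; ``histogram`` fits
    the normalized histogram by least squares for comparison. A one-sample
    Kolmogorov–Smirnov statistic against the fitted exponential is attached
    as a goodness-of-fit diagnostic.
    """
    gaps = np.asarray(gaps_um, dtype=float)
    if gaps.size < min_gaps:
        raise ValueError(f"need at least {min_gaps} gaps, got {gaps.size}")
    if np.any(gaps <= 0):
        raise ValueError("all gaps must be positive")
    if method == "mle":
        rate = 1.0 / float(gaps.mean())
    elif method == "histogram":
        density, edges = np.histogram(gaps, bins=n_hist_bins, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        (rate,), _ = curve_fit(
            lambda x, lam: lam * np.exp(-lam * x), centers, density, p0=[1.0 / gaps.mean()]
        )
        rate = float(rate)
    else:
        raise ValueError(f"unknown fit method {method!r}")
    ks = kstest(gaps, "expon", args=(0.0, 1.0 / rate))
    return PoreSizeResult(
        gaps_um=gaps,
        rate_per_um=rate,
        n_gaps=int(gaps.size),
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
    )


def pore_size_pipeline(
    images: PixelImage | Sequence[PixelImage],
    config: PoreConfig = PoreConfig(),
) -> PoreSizeResult | list[PoreSizeResult]:
    """Full estimator: preprocess → binarize → count gaps → exponential fit.

    A single configuration applies to every image in the batch (the
    uniform-workflow rule is enforced by the API). With
    ``config.pool_images`` (default) gaps from all images are pooled into
    one fit; otherwise one result per image is returned.
    """
    if isinstance(images, PixelImage):
        images = [images]
    per_image_gaps = []
    for img in images:
        pre = preprocess(
            img,
            config.bandpass_small_px,
            config.bandpass_large_px,
            config.rollingball_radius_px,
        )
        net = binarize(pre, method=config.threshold_method, window_px=config.window_px)
        per_image_gaps.append(count_gaps(net, include_border=config.include_border_gaps))
    if config.pool_images:
        return fit_exponential(
            np.concatenate(per_image_gaps), min_gaps=config.min_gaps, method=config.fit_method
        )
    return [
        fit_exponential(g, min_gaps=config.min_gaps, method=config.fit_method)
        for g in per_image_gaps
    ]
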