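"""Mass spectrometry imaging (DESI) quantification.

An :class:`MSICube` stores per-pixel profile-mode spectra on one shared,
strictly increasing m/z axis (continuous mode). Quantification follows the
acquisition/processing conventions of DESI imaging of spheroid sections:
total-ion-current (TIC) normalization, mean intensity in m/z windows over a
section mask, ppm-tolerance ion images, and annotation of observed peaks
against a user-supplied monoisotopic mass table at a 5 ppm tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .stats import compare_groups

__all__ = [
    "MSICube",
    "IonImage",
    "WindowStat",
    "tic_normalize",
    "window_mean",
    "temperature_series",
    "ion_image",
    "annotate",
    "section_mask_from_tic",
]


@dataclass
class MSICube:
    """Pixel grid of mass spectra sharing one m/z axis.

    ``intensities`` has shape ``(rows, cols, n_bins)``; ``mz`` is the shared
    strictly increasing axis. ``mask`` marks valid pixels (zero-TIC pixels
    are masked out by normalization).
    """

    mz: np.ndarray
    intensities: np.ndarray
    pixel_size_um: float
    mask: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.asarray(self.intensities)
        if self.mz.ndim != 1 or np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z axis must be 1D and strictly increasing")
        if self.intensities.ndim != 3 or self.intensities.shape[2] != self.mz.size:
            raise ValueError("intensities must be (rows, cols, n_bins) matching the m/z axis")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if self.mask is None:
            self.mask = np.ones(self.intensities.shape[:2], dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape[:2]

    @property
    def mass_range(self) -> tuple[float, float]:
        return float(self.mz[0]), float(self.mz[-1])

    def tic(self) -> np.ndarray:
        """Total ion current per pixel."""
        return self.intensities.sum(axis=2)


@dataclass
class IonImage:
    """Per-pixel integrated intensity in a ppm window around a target m/z."""

    target_mz: float
    ppm: float
    image: np.ndarray
    normalization: str = "tic"

    @property
    def window(self) -> tuple[float, float]:
        half = self.target_mz * self.ppm * 1e-6
        return (self.target_mz - half, self.target_mz + half)


@dataclass
class WindowStat:
    """Mean (normalized) intensity in an m/z window over a section mask."""

    window: tuple[float, float]
    mean_intensity: float
    n_pixels: int
    group: str = ""
    per_pixel: np.ndarray | None = None


def section_mask_from_tic(cube: MSICube, fraction_of_max: float = 0.05) -> np.ndarray:
    """Automatic section mask: pixels whose TIC exceeds a fraction of the maximum."""
    tic = cube.tic()
    return tic > fraction_of_max * tic.max()


def tic_normalize(cube: MSICube) -> MSICube:
    """Divide each pixel's spectrum by its total ion current.

    After normalization every unmasked pixel's spectrum sums to exactly 1.
    Pixels with zero TIC are masked (not divided) and counted in a warning.
    """
    tic = cube.tic()
    zero = tic <= 0
    n_zero = int(np.count_nonzero(zero & cube.mask))
    if n_zero:
        warnings.warn(f"{n_zero} zero-TIC pixel(s) masked during TIC normalization")
    safe = np.where(zero, 1.0, tic)
    data = cube.intensities / safe[..., None]
    data[zero] = 0.0
    meta = dict(cube.meta, normalization="tic")
    return MSICube(cube.mz, data, cube.pixel_size_um, mask=cube.mask & ~zero, meta=meta)


def _window_slice(mz: np.ndarray, lo: float, hi: float) -> slice:
    # closed window: bins with lo <= m/z <= hi
    i0 = np.searchsorted(mz, lo, side="left")
    i1 = np.searchsorted(mz, hi, side="right")
    return slice(int(i0), int(i1))


def window_mean(
    cube: MSICube,
    window: tuple[float, float],
    section_mask: np.ndarray | None = None,
    group: str = "",
) -> WindowStat:
    """Mean over masked pixels of the summed intensity inside an m/z window."""
    lo, hi = window
    if not lo < hi:
        raise ValueError("window must satisfy lo < hi")
    if lo < cube.mz[0] or hi > cube.mz[-1]:
        raise ValueError(f"window {window} outside mass range {cube.mass_range}")
    mask = cube.mask if section_mask is None else (np.asarray(section_mask, bool) & cube.mask)
    if not mask.any():
        raise ValueError("section mask selects no valid pixels")
    sl = _window_slice(cube.mz, lo, hi)
    per_pixel = cube.intensities[..., sl].sum(axis=2)
    vals = per_pixel[mask]
    return WindowStat(
        window=(float(lo), float(hi)),
        mean_intensity=float(vals.mean()),
        n_pixels=int(vals.size),
        group=group,
        per_pixel=per_pixel,
    )


def temperature_series(
    stats: Sequence[WindowStat] | dict[str, Sequence[float]],
    alpha: float = 0.05,
    method: str = "welch",
) -> pd.DataFrame:
    """Pairwise comparison of window statistics grouped by condition label.

    Accepts either per-section :class:`WindowStat` objects (grouped by their
    ``group`` label, e.g. the transfer-capillary temperature) or an explicit
    mapping label -> per-section values. Groups with n < 2 are excluded with
    a warning.
    """
    if isinstance(stats, dict):
        groups = {str(k): list(v) for k, v in stats.items()}
    else:
        groups = {}
        for s in stats:
            groups.setdefault(str(s.group), []).append(s.mean_intensity)
    keep = {}
    for k, v in groups.items():
        if len(v) < 2:
            warnings.warn(f"group {k!r} has n < 2 and is excluded")
        else:
            keep[k] = v
    return compare_groups(keep, alpha=alpha, method=method)


def ion_image(
    cube: MSICube,
    target_mz: float,
    ppm: float = 5.0,
    normalization: str = "tic",
) -> IonImage:
    """Integrate each pixel's spectrum over a ppm window around a target ion.

    ``normalization="tic"`` TIC-normalizes first (no-op if the cube already
    is); ``"none"`` integrates raw intensities.
    """
    if not cube.mz[0] <= target_mz <= cube.mz[-1]:
        raise ValueError(f"target m/z {target_mz} outside mass range {cube.mass_range}")
    half = target_mz * ppm * 1e-6
    lo, hi = target_mz - half, target_mz + half
    if lo < cube.mz[0] or hi > cube.mz[-1]:
        raise ValueError("ppm window exits the mass range")
    if normalization == "tic" and cube.meta.get("normalization") != "tic":
        cube = tic_normalize(cube)
    sl = _window_slice(cube.mz, lo, hi)
    img = cube.intensities[..., sl].sum(axis=2)
    return IonImage(target_mz=float(target_mz), ppm=float(ppm), image=img, normalization=normalization)


def annotate(
    peaks: Sequence[float],
    mass_table: pd.DataFrame | Sequence[tuple[str, float]],
    ppm: float = 5.0,
) -> pd.DataFrame:
    """Match observed m/z peaks against a monoisotopic mass table.

    Every table entry within ``ppm`` tolerance of a peak is reported;
    ambiguous (multiple) matches are all returned, never resolved. The mass
    table replaces online database lookup and is supplied by the user as
    ``(name, mz)`` pairs or a DataFrame with ``name``/``mz`` columns.
    """
    if isinstance(mass_table, pd.DataFrame):
        table = mass_table[["name", "mz"]].copy()
    else:
        table = pd.DataFrame(list(mass_table), columns=["name", "mz"])
    if table.empty:
        raise ValueError("mass table is empty")
    rows = []
    for peak in peaks:
        err_ppm = (peak - table["mz"].to_numpy()) / table["mz"].to_numpy() * 1e6
        hits = np.abs(err_ppm) <= ppm
        if not hits.any():
            rows.append({"observed_mz": float(peak), "name": None, "theoretical_mz": np.nan, "ppm_error": np.nan})
        for i in np.flatnonzero(hits):
            rows.append(
                {
                    "observed_mz": float(peak),
                    "name": table["name"].iloc[i],
                    "theoretical_mz": float(table["mz"].iloc[i]),
                    "ppm_error": float(err_ppm[i]),
                }
            )
    return pd.DataFrame(rows)
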