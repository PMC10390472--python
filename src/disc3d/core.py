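"""Shared containers and infrastructure.

Physical coordinates are carried in micrometres (μm) for images and in
nanometres (nm) for single-molecule localizations; every container records
its pixel size so downstream morphometry never guesses units. The image
origin is the centre of the top-left pixel, arrays are row-major
(row = y, column = x), and ``pixel index = floor(position / pixel_size)``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = [
    "PixelImage",
    "CameraModel",
    "child_seed",
    "fwhm_to_sigma",
    "sigma_to_fwhm",
    "GAUSSIAN_FWHM_FACTOR",
]

#: FWHM / sigma ratio of a Gaussian: 2 * sqrt(2 * ln 2).
GAUSSIAN_FWHM_FACTOR: float = 2.0 * np.sqrt(2.0 * np.log(2.0))


def sigma_to_fwhm(sigma: float) -> float:
    """Full width at half maximum of a Gaussian with standard deviation ``sigma``."""
    return GAUSSIAN_FWHM_FACTOR * float(sigma)


def fwhm_to_sigma(fwhm: float) -> float:
    return float(fwhm) / GAUSSIAN_FWHM_FACTOR


def child_seed(seed: int, name: str) -> int:
    """Derive a stable per-stage seed from a global seed.

    Uses BLAKE2 hashing so that adding or reordering stages never shifts
    another stage's random stream. Result is always < 2**31.
    """
    h = hashlib.blake2b(f"{seed}:{name}".encode(), digest_size=8)
    return int.from_bytes(h.digest(), "little") % (2**31)


@dataclass
class PixelImage:
    """A 2D (or 2D multichannel / 3D stack) intensity array with physical pixel size.

    Parameters
    ----------
    data:
        Intensity array. 2D ``(rows, cols)`` for a single-channel image;
        higher-dimensional data keeps the two trailing axes spatial.
    pixel_size_um:
        Edge length of one pixel in micrometres (isotropic).
    meta:
        Free-form metadata (channel names, depth, modality, ...).
    """

    data: np.ndarray
    pixel_size_um: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.data.ndim < 2:
            raise ValueError("image data must be at least 2-dimensional")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def pixel_size_nm(self) -> float:
        return self.pixel_size_um * 1e3

    @property
    def field_size_um(self) -> tuple[float, float]:
        """(height, width) of the image in μm."""
        return (
            self.data.shape[-2] * self.pixel_size_um,
            self.data.shape[-1] * self.pixel_size_um,
        )

    def with_data(self, data: np.ndarray) -> "PixelImage":
        return replace(self, data=np.asarray(data))

    def to_physical(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Pixel indices -> physical coordinates (μm) of pixel centres."""
        return np.asarray(row) * self.pixel_size_um, np.asarray(col) * self.pixel_size_um

    def to_pixel(self, y_um: np.ndarray, x_um: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Physical coordinates (μm) -> integer pixel indices (floor convention)."""
        return (
            np.floor(np.asarray(y_um) / self.pixel_size_um).astype(int),
            np.floor(np.asarray(x_um) / self.pixel_size_um).astype(int),
        )


@dataclass(frozen=True)
class CameraModel:
    """EMCCD/sCMOS gain model converting photons to analog-digital units.

    Defaults are the acquisition constants of the sCMOS camera used for
    STORM: 97 nm effective pixel, 0.46 photoelectrons per A/D count and a
    baseline of 97 counts.
    """

    pixel_size_nm: float = 97.0
    photoelectrons_per_adu: float = 0.46
    baseline_adu: float = 97.0
    read_noise_e: float = 1.6

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.photoelectrons_per_adu <= 0:
            raise ValueError("photoelectrons_per_adu must be positive")

    def photons_to_adu(
        self,
        photons: np.ndarray,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Forward camera model. With ``rng`` applies shot + read noise."""
        photons = np.asarray(photons, dtype=float)
        if rng is not None:
            electrons = rng.poisson(np.clip(photons, 0, None)).astype(float)
            adu = electrons / self.photoelectrons_per_adu + self.baseline_adu
            adu = adu + rng.normal(0.0, self.read_noise_e / self.photoelectrons_per_adu, photons.shape)
        else:
            adu = photons / self.photoelectrons_per_adu + self.baseline_adu
        return adu

    def adu_to_photons(self, adu: np.ndarray) -> np.ndarray:
        """Inverse camera model; counts below baseline clamp to zero photons."""
        adu = np.asarray(adu, dtype=float)
        return np.clip(adu - self.baseline_adu, 0.0, None) * self.photoelectrons_per_adu
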