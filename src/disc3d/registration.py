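"""Intensity-based rigid/similarity registration across modalities.

Registers images of the same physical section acquired on different
instruments (optical ↔ optical, optical ↔ MSI) without fiducial markers:
a coarse rotation grid with FFT cross-correlation for translation, then
simplex refinement of a normalized-cross-correlation objective. Pixel
sizes may differ by large factors (40 μm MSI vs sub-μm confocal); the
search runs on a common grid at the coarser of the two resolutions and the
result is expressed in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .core import PixelImage

__all__ = ["RigidTransform", "RegistrationError", "register", "warp_to_grid", "overlay"]


class RegistrationError(RuntimeError):
    """Raised when no credible correlation peak is found."""

    def __init__(self, message: str, score: float):
        super().__init__(f"{message} (score = {score:.3f})")
        self.score = score


@dataclass(frozen=True)
class RigidTransform:
    """Similarity transform in physical units: p' = s·R(θ)·p + t.

    ``theta_deg`` is counter-clockwise rotation in the (x, y) plane,
    ``(tx_um, ty_um)`` the translation, ``scale`` an optional isotropic
    factor (1 for a rigid transform).
    """

    theta_deg: float
    tx_um: float
    ty_um: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def rotation_matrix(self) -> np.ndarray:
        """2×2 matrix acting on (x, y) column vectors."""
        c, s = np.cos(np.radians(self.theta_deg)), np.sin(np.radians(self.theta_deg))
        return np.array([[c, -s], [s, c]])

    @classmethod
    def about_center(
        cls, theta_deg: float, tx_um: float, ty_um: float, center_um: tuple[float, float], scale: float = 1.0
    ) -> "RigidTransform":
        """Rotation about an explicit centre folded into canonical form."""
        c = np.asarray(center_um, float)
        rot = cls(theta_deg, 0.0, 0.0, scale).rotation_matrix * scale
        t = c + np.array([tx_um, ty_um]) - rot @ c
        return cls(theta_deg, float(t[0]), float(t[1]), scale)

    def apply(self, points_um: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_um, float))
        return (self.scale * (self.rotation_matrix @ pts.T)).T + np.array([self.tx_um, self.ty_um])

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        rot = self.scale * self.rotation_matrix
        t = rot @ np.array([other.tx_um, other.ty_um]) + np.array([self.tx_um, self.ty_um])
        return RigidTransform(
            self.theta_deg + other.theta_deg, float(t[0]), float(t[1]), self.scale * other.scale
        )

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation_matrix.T / self.scale
        t = -rinv @ np.array([self.tx_um, self.ty_um])
        return RigidTransform(-self.theta_deg, float(t[0]), float(t[1]), 1.0 / self.scale)


def _resample(image: PixelImage, pixel_size_um: float) -> np.ndarray:
    zoom = image.pixel_size_um / pixel_size_um
    data = image.data.astype(float)
    if np.isclose(zoom, 1.0):
        return data
    if zoom < 1.0:
        # anti-alias before downsampling
        data = ndimage.gaussian_filter(data, 0.5 / zoom)
    return ndimage.zoom(data, zoom, order=1)


def _normalize(img: np.ndarray) -> np.ndarray:
    out = img - img.mean()
    norm = np.linalg.norm(out)
    return out / norm if norm > 0 else out


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def warp_to_grid(
    moving: PixelImage,
    transform: RigidTransform,
    grid_shape: tuple[int, int],
    grid_pixel_size_um: float,
) -> np.ndarray:
    """Resample ``transform(moving)`` onto a target grid (bilinear)."""
    inv = transform.inverse()
    rot_xy = inv.scale * inv.rotation_matrix
    # output pixel (i, j) centre -> physical (x, y) -> moving physical -> moving pixel
    # row/col ordering: [y, x] = P @ [x, y] with P the axis swap
    m_yx = np.array([[rot_xy[1, 1], rot_xy[1, 0]], [rot_xy[0, 1], rot_xy[0, 0]]])
    ps_o, ps_m = grid_pixel_size_um, moving.pixel_size_um
    matrix = m_yx * (ps_o / ps_m)
    t_yx = np.array([inv.ty_um, inv.tx_um])
    offset = m_yx @ np.array([0.5 * ps_o, 0.5 * ps_o]) / ps_m + t_yx / ps_m - 0.5
    return ndimage.affine_transform(
        moving.data.astype(float), matrix, offset=offset, output_shape=grid_shape, order=1, mode="constant"
    )


def register(
    moving: PixelImage,
    fixed: PixelImage,
    model: str = "rigid",
    coarse_range_deg: float = 20.0,
    coarse_step_deg: float = 1.0,
    score_threshold: float = 0.1,
) -> tuple[RigidTransform, PixelImage, float]:
    """Find the transform aligning ``moving`` to ``fixed``.

    Search: resample both images to the coarser pixel size, scan rotations
    on a ±``coarse_range_deg`` grid with FFT cross-correlation giving the
    best translation per rotation, then refine (θ, tx, ty and, for
    ``model="similarity"``, scale) with Nelder–Mead on the normalized
    cross-correlation. Returns the transform (physical units), the moving
    image resampled onto the fixed grid, and the final NCC score.
    """
    if model not in ("rigid", "similarity"):
        raise ValueError(f"unknown model {model!r}")
    ps = max(fixed.pixel_size_um, moving.pixel_size_um)
    f = _resample(fixed, ps)
    m = _resample(moving, ps)
    shape = (max(f.shape[0], m.shape[0]), max(f.shape[1], m.shape[1]))
    fp = np.zeros(shape)
    fp[: f.shape[0], : f.shape[1]] = f
    center_um = (shape[1] * ps / 2, shape[0] * ps / 2)

    # FFT cross-correlation with 2x zero padding against circular wrap
    pad = (2 * shape[0], 2 * shape[1])
    Ff = np.fft.rfft2(_normalize(fp), pad)
    best = (-np.inf, 0.0, 0.0, 0.0)  # score, theta, tx, ty
    thetas = np.arange(-coarse_range_deg, coarse_range_deg + coarse_step_deg / 2, coarse_step_deg)
    for theta in thetas:
        trial = RigidTransform.about_center(theta, 0.0, 0.0, center_um)
        mr = warp_to_grid(PixelImage(m, ps), trial, shape, ps)
        cc = np.fft.irfft2(Ff * np.conj(np.fft.rfft2(_normalize(mr), pad)), pad)
        idx = np.unravel_index(np.argmax(cc), cc.shape)
        dy = idx[0] if idx[0] <= pad[0] // 2 else idx[0] - pad[0]
        dx = idx[1] if idx[1] <= pad[1] // 2 else idx[1] - pad[1]
        score = float(cc[idx])
        if score > best[0]:
            best = (score, theta, dx * ps, dy * ps)

    # refine against the fixed image at its native resolution: the moving
    # image is warped straight onto the fixed grid per evaluation, so the
    # objective keeps full precision even when the search grid was coarse
    fixed_native = fixed.data.astype(float)
    fixed_shape = fixed_native.shape[-2:]

    def objective(params: np.ndarray) -> float:
        theta, tx, ty = params[:3]
        scale = np.exp(params[3]) if model == "similarity" else 1.0
        t = RigidTransform.about_center(theta, tx, ty, center_um, scale)
        w = warp_to_grid(moving, t, fixed_shape, fixed.pixel_size_um)
        return -_ncc(fixed_native, w)

    x0 = [best[1], best[2], best[3]] + ([0.0] if model == "similarity" else [])
    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"xatol": 0.02, "fatol": 1e-6, "maxiter": 400},
    )
    score = -float(res.fun)
    if score < score_threshold:
        raise RegistrationError("no credible correlation peak", score)
    theta, tx, ty = res.x[:3]
    scale = float(np.exp(res.x[3])) if model == "similarity" else 1.0
    transform = RigidTransform.about_center(float(theta), float(tx), float(ty), center_um, scale)
    registered = PixelImage(
        warp_to_grid(moving, transform, fixed.data.shape[-2:], fixed.pixel_size_um),
        fixed.pixel_size_um,
        meta={"registered_to": "fixed", "score": score},
    )
    return transform, registered, score


_COLORS = {
    "red": (1, 0, 0),
    "green": (0, 1, 0),
    "blue": (0, 0, 1),
    "magenta": (1, 0, 1),
    "cyan": (0, 1, 1),
    "yellow": (1, 1, 0),
    "gray": (1, 1, 1),
}


def overlay(
    fixed: PixelImage,
    registered: PixelImage,
    color_map: tuple[str, str] = ("magenta", "green"),
) -> np.ndarray:
    """Channel-composited RGB overlay of two images on the same grid.

    Each input is linearly scaled to [0, 1] and tinted with its colour; the
    composite is the clipped sum, so identical images in complementary
    colours look grayscale.
    """
    if fixed.data.shape != registered.data.shape:
        raise ValueError("overlay requires images on the same grid")
    rgb = np.zeros((*fixed.data.shape, 3))
    for img, cname in ((fixed, color_map[0]), (registered, color_map[1])):
        data = img.data.astype(float)
        rng_ = data.max() - data.min()
        norm = (data - data.min()) / rng_ if rng_ > 0 else np.zeros_like(data)
        rgb += norm[..., None] * np.asarray(_COLORS[cname], dtype=float)
    return np.clip(rgb, 0.0, 1.0)
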