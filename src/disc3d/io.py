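"""Standard-format I/O: TIFF images, localization CSV, imzML / NPZ cubes.

Pixel sizes are written into the files themselves (TIFF description JSON,
NPZ arrays) so round trips are lossless; where a format cannot carry the
pixel size it must be supplied explicitly on read — there is no silent
unit guessing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import PixelImage
from .msi import MSICube
from .smlm import LOCALIZATION_COLUMNS, DriftTrace, LocalizationTable

__all__ = [
    "write_image",
    "read_image",
    "write_localizations",
    "read_localizations",
    "write_drift",
    "read_drift",
    "write_msi_npz",
    "read_msi_npz",
    "write_msi_imzml",
    "read_msi_imzml",
    "write_transform",
    "read_transform",
]


def write_image(path: str | Path, image: PixelImage) -> Path:
    """Write a TIFF with the pixel size embedded in the description tag."""
    path = Path(path)
    desc = json.dumps({"pixel_size_um": image.pixel_size_um})
    tifffile.imwrite(path, image.data, description=desc)
    return path


def read_image(path: str | Path, pixel_size_um: float | None = None) -> PixelImage:
    """Read a TIFF; pixel size comes from its metadata or must be given."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    if pixel_size_um is None:
        try:
            pixel_size_um = json.loads(desc)["pixel_size_um"]
        except (json.JSONDecodeError, KeyError, TypeError):
            raise ValueError(
                f"{path} carries no pixel-size metadata; pass pixel_size_um explicitly"
            ) from None
    return PixelImage(data, pixel_size_um=float(pixel_size_um))


def write_localizations(path: str | Path, table: LocalizationTable) -> Path:
    path = Path(path)
    cols = LOCALIZATION_COLUMNS + [c for c in table.df.columns if c not in LOCALIZATION_COLUMNS]
    table.df[cols].to_csv(path, index=False)
    return path


def read_localizations(path: str | Path) -> LocalizationTable:
    return LocalizationTable(pd.read_csv(path))


def write_drift(path: str | Path, trace: DriftTrace) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "bin_center_frame": trace.bin_center_frames,
            "dx_nm": trace.bin_dx_nm,
            "dy_nm": trace.bin_dy_nm,
        }
    ).to_csv(path, index=False)
    return path


def read_drift(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_msi_npz(path: str | Path, cube: MSICube) -> Path:
    """NPZ array bundle: m/z axis, intensity cube, mask, pixel size."""
    path = Path(path)
    np.savez_compressed(
        path,
        mz=cube.mz,
        intensities=cube.intensities,
        mask=cube.mask,
        pixel_size_um=np.array([cube.pixel_size_um]),
    )
    return path


def read_msi_npz(path: str | Path) -> MSICube:
    with np.load(path) as z:
        return MSICube(
            z["mz"], z["intensities"], float(z["pixel_size_um"][0]), mask=z["mask"].astype(bool)
        )


def write_msi_imzml(path: str | Path, cube: MSICube) -> Path:
    """Continuous-mode imzML (shared m/z axis, float32 intensities)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = Path(path)
    with ImzMLWriter(str(path), mode="continuous") as writer:
        ny, nx = cube.shape
        for iy in range(ny):
            for ix in range(nx):
                writer.addSpectrum(
                    cube.mz, cube.intensities[iy, ix].astype(np.float32), (ix + 1, iy + 1, 1)
                )
    return path


def read_msi_imzml(path: str | Path, pixel_size_um: float) -> MSICube:
    """Read a continuous-mode imzML file onto the shared-axis cube container."""
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    coords = np.asarray(parser.coordinates)
    nx = int(coords[:, 0].max())
    ny = int(coords[:, 1].max())
    mz0, _ = parser.getspectrum(0)
    data = np.zeros((ny, nx, len(mz0)), dtype=float)
    for i, (x, y, _z) in enumerate(parser.coordinates):
        _mz, intens = parser.getspectrum(i)
        data[y - 1, x - 1] = intens
    return MSICube(np.asarray(mz0, float), data, pixel_size_um)


def write_transform(path: str | Path, transform) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(
            {
                "theta_deg": transform.theta_deg,
                "tx_um": transform.tx_um,
                "ty_um": transform.ty_um,
                "scale": transform.scale,
            },
            indent=2,
        )
    )
    return path


def read_transform(path: str | Path):
    from .registration import RigidTransform

    d = json.loads(Path(path).read_text())
    return RigidTransform(d["theta_deg"], d["tx_um"], d["ty_um"], d.get("scale", 1.0))
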