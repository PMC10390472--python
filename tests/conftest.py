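import numpy as np
import pytest

from disc3d.core import CameraModel
from disc3d.phantoms import FiberNetworkPhantom, FiberSegment


@pytest.fixture
def camera() -> CameraModel:
    """STORM acquisition constants: 97 nm px, 0.46 e-/ADU, 97 ADU baseline."""
    return CameraModel()


@pytest.fixture
def single_fiber_phantom() -> FiberNetworkPhantom:
    """One horizontal fiber with true cross-section sigma = 31.85 nm (FWHM 75 nm)."""
    return FiberNetworkPhantom(
        fibers=[FiberSegment((0.0, 2.0), (4.0, 2.0), sigma_nm=31.85)],
        field_size_um=(4.0, 4.0),
        pixel_size_um=0.01,
        seed=11,
    )


@pytest.fixture
def gap_phantom() -> FiberNetworkPhantom:
    """Small axis-aligned network with exponential clear gaps at rate 1/3 per um."""
    return FiberNetworkPhantom.grid(
        field_size_um=(120.0, 120.0),
        pixel_size_um=0.1,
        gap_rate_per_um=1 / 3,
        sigma_nm=130.0,
        orientation="cross",
        seed=4,
    )


def brute_force_dbscan_noise(xy: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Independent O(n^2) DBSCAN membership oracle.

    Returns a boolean mask of points that belong to some cluster (i.e. are
    not noise): core points have >= min_pts neighbours within eps (self
    included); border points lie within eps of a core point.
    """
    n = len(xy)
    d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
    neighbour = d <= eps
    core = neighbour.sum(axis=1) >= min_pts
    member = core.copy()
    for i in range(n):
        if not member[i] and neighbour[i][core].any():
            member[i] = True
    return member
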