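import numpy as np
import pytest

from mitometry.core import Calibration, LabelMap


@pytest.fixture
def cal2d():
    return Calibration(px_x_nm=10.0, px_y_nm=10.0)


@pytest.fixture
def cal3d():
    return Calibration(px_x_nm=10.0, px_y_nm=10.0, px_z_nm=10.0)


@pytest.fixture
def cal3d_aniso():
    # typical volume-EM pitch: 10 nm in-plane, 50 nm slices
    return Calibration(px_x_nm=10.0, px_y_nm=10.0, px_z_nm=50.0)


@pytest.fixture
def two_blob_map(cal2d):
    arr = np.zeros((40, 40), dtype=np.uint8)
    arr[5:15, 5:15] = 1
    arr[22:30, 20:35] = 2
    return LabelMap(arr, "mitochondrion", cal2d)


def tube_mask_3d(shape, segments, radius_vox):
    """Union of capsule segments; segments are ((z,y,x), (z,y,x)) pairs."""
    z = np.arange(shape[0])[:, None, None].astype(float)
    y = np.arange(shape[1])[None, :, None].astype(float)
    x = np.arange(shape[2])[None, None, :].astype(float)
    mask = np.zeros(shape, dtype=bool)
    for p0, p1 in segments:
        p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
        d = p1 - p0
        length = np.linalg.norm(d)
        u = d / length
        pz, py, px = z - p0[0], y - p0[1], x - p0[2]
        t = np.clip(pz * u[0] + py * u[1] + px * u[2], 0.0, length)
        dist2 = (pz - t * u[0]) ** 2 + (py - t * u[1]) ** 2 + (px - t * u[2]) ** 2
        mask |= dist2 <= radius_vox**2
    return mask
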