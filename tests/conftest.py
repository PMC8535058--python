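"""Shared fixtures: synthetic tubes and phantoms, generated at test time."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.spatial import cKDTree

from pclt2.io import MultiEchoVolume
from pclt2.phantom import ECHO_TIMES_MS, PhantomSpec, generate_phantom
from pclt2.relaxometry import fit_t2_pixelwise

SPACING = (3.2, 0.4, 0.4)


@pytest.fixture(scope="session")
def echo_times():
    return np.asarray(ECHO_TIMES_MS)


def make_volume(signal, echo_times=None, spacing=SPACING, **kw):
    te = np.asarray(ECHO_TIMES_MS if echo_times is None else echo_times)
    return MultiEchoVolume(signal=np.asarray(signal, float), echo_times=te,
                           voxel_spacing=spacing, **kw)


def straight_tube(length=40.0, radius=3.0, shape=(9, 60, 130), spacing=SPACING,
                  x_start=4.0):
    """Axis-aligned cylinder with flat caps; returns (mask, spacing)."""
    dz, dy, dx = spacing
    nz, ny, nx = shape
    zz, yy, xx = np.meshgrid(np.arange(nz) * dz, np.arange(ny) * dy,
                             np.arange(nx) * dx, indexing="ij")
    zc, yc = (nz // 2) * dz, (ny // 2) * dy
    r = np.sqrt((zz - zc) ** 2 + (yy - yc) ** 2)
    return (r <= radius) & (xx >= x_start) & (xx <= x_start + length)


def curved_tube(curve_points, radius=3.0, shape=(9, 120, 120), spacing=SPACING):
    """Tube of given radius around a dense polyline, flat end caps."""
    dz, dy, dx = spacing
    nz, ny, nx = shape
    zz, yy, xx = np.meshgrid(np.arange(nz) * dz, np.arange(ny) * dy,
                             np.arange(nx) * dx, indexing="ij")
    vox = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)
    d, idx = cKDTree(curve_points).query(vox)
    interior = (idx > 0) & (idx < len(curve_points) - 1)
    return ((d <= radius) & interior).reshape(nz, ny, nx)


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def noiseless_spec(default_spec):
    return replace(default_spec, noise_sigma_frac=0.0)


@pytest.fixture(scope="session")
def noiseless_d0(noiseless_spec):
    return generate_phantom(noiseless_spec, "d0")


@pytest.fixture(scope="session")
def noiseless_d1(noiseless_spec):
    return generate_phantom(noiseless_spec, "d1")


@pytest.fixture(scope="session")
def noisy_d0(default_spec):
    return generate_phantom(default_spec, "d0")


@pytest.fixture(scope="session")
def fitted_noisy_d0(noisy_d0):
    vol, mask, gt = noisy_d0
    return fit_t2_pixelwise(vol, mask.labels > 0), mask, gt
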