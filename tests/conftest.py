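import numpy as np
import pytest
import tifffile

from devils import DevilsParams, DiskGridSpec, LazyStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """Parameters scaled for desk-size test planes."""
    return DevilsParams(p=4, division_scale=100.0)


@pytest.fixture
def tiny_grid_spec():
    """A 3x3 disk grid small enough for fast unit tests (includes I=20)."""
    return DiskGridSpec(
        intensities=(5.0, 20.0, 100.0),
        diameters=(5.0, 7.0, 11.0),
        cell_size=24,
        margin=6,
        noise_sd=0.0,
    )


def bell_stack(n_z=9, size=48, seed=0):
    """Synthetic stack whose per-plane mean follows a bell curve along z,
    emulating light attenuation towards the top and bottom of a volume."""
    rng = np.random.default_rng(seed)
    z = np.arange(n_z)
    bell = np.exp(-((z - (n_z - 1) / 2.0) ** 2) / (2.0 * (n_z / 4.0) ** 2))
    base = np.full((size, size), 2.0)
    yy, xx = np.mgrid[0:size, 0:size]
    centers = [(12, 12), (12, 36), (36, 12), (36, 36), (24, 24)]
    data = np.empty((n_z, size, size))
    for k in range(n_z):
        plane = base.copy()
        for cy, cx in centers:
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 < 4.0**2
            plane[mask] += 200.0 * bell[k]
        plane += rng.normal(0, 0.3, plane.shape)
        data[k] = np.clip(plane, 0, None)
    return data


@pytest.fixture
def memory_stack(rng):
    """4D (c, z) in-memory stack of random planes."""
    data = (rng.random((2, 4, 24, 24)) * 200).astype(np.uint16)
    return LazyStack.from_array(data, axes="CZYX"), data


def write_stack_tiff(path, data, axes=None):
    kwargs = {"photometric": "minisblack"}
    if axes is not None:
        kwargs["metadata"] = {"axes": axes}
    tifffile.imwrite(path, data, **kwargs)
    return path
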