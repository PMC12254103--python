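"""Shared fixtures: compact phantoms and pre-rasterized images.

Geometry in the tests is deliberately smaller than the full scanner matrix —
real sphere sizes and voxel pitches, but compact bodies and cropped grids —
so every image-domain test runs in seconds.
"""

import numpy as np
import pytest

import phantomiq as pq

#: background VOI center used with the small 3-sphere phantom: posterior,
#: central in z so motion blur from the body caps cannot reach it, and
#: geometrically clear of all spheres.
SMALL_BG_CENTER = (0.0, -30.0, 0.0)


@pytest.fixture(scope="session")
def small_phantom():
    """Compact 3-sphere phantom: 10, 17 and 28 mm spheres in a small body.

    Spheres sit in the anterior half; the posterior half is clean
    background for the fixed background VOI."""
    body = pq.BodySpec(semi_axis_x=60.0, semi_axis_y=55.0, length=100.0)
    spheres = ((10.0, (25.0, 10.0, 0.0)),
               (17.0, (-25.0, 10.0, 0.0)),
               (28.0, (0.0, 32.0, 0.0)))
    return pq.PhantomSpec(spheres=spheres, background_activity=2.0, tbr=5.0,
                          body=body)


@pytest.fixture(scope="session")
def small_grid():
    return pq.GridSpec.centered((160.0, 150.0, 140.0))


@pytest.fixture(scope="session")
def small_truth(small_phantom, small_grid):
    """Noise-free rasterized small phantom (ground truth)."""
    return pq.rasterize_phantom(small_phantom, small_grid, supersample=2)


@pytest.fixture(scope="session")
def small_static(small_truth):
    """Static acquisition: PSF only, no motion, no noise."""
    return pq.apply_psf(small_truth, fwhm=5.0)


@pytest.fixture(scope="session")
def default_phantom():
    """Full six-sphere phantom at NEMA scale (default geometry)."""
    return pq.PhantomSpec(background_activity=2.0, tbr=5.0)


@pytest.fixture(scope="session")
def default_static(default_phantom):
    """Noise-free, motion-free acquisition of the full six-sphere phantom."""
    grid = pq.ExperimentConfig(phantom=default_phantom).resolved_grid()
    truth = pq.rasterize_phantom(default_phantom, grid, supersample=2)
    return pq.apply_psf(truth, fwhm=5.0)


@pytest.fixture(scope="session")
def tiny_experiment_config(small_phantom):
    """Reduced factorial design exercising the full pipeline in seconds."""
    return pq.ExperimentConfig(
        phantom=small_phantom,
        grid=pq.GridSpec.centered((160.0, 150.0, 140.0)),
        tbrs=(2.0, 5.0),
        amplitudes=(0.0, 10.0),
        noise_level=0.15,
        master_seed=7,
        correction_iterations=25,
        supersample=2,
        background_voi_center_mm=SMALL_BG_CENTER,
    )


def delta_image(shape=(41, 41, 41), voxel=(1.0, 1.0, 1.0), value=1.0):
    """Unit impulse at the grid center."""
    grid = pq.GridSpec(shape=shape, voxel_size=voxel,
                       origin=tuple(-(n - 1) / 2 * v for n, v in zip(shape, voxel)))
    values = np.zeros(shape)
    values[tuple(n // 2 for n in shape)] = value
    return pq.VoxelImage(grid=grid, values=values)
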