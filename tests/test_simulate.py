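"""Motion kernel, blur, PSF and noise emulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phantomiq as pq


def time_stepped_kernel(amplitude, pitch, n_steps=100_000):
    """Independent dwell oracle: step the triangular-wave trajectory through
    one full cycle and histogram the positions into voxel-pitch bins."""
    phase = (np.arange(n_steps) + 0.5) / n_steps
    # triangle wave covering [-A/2, A/2] twice per cycle
    pos = amplitude * (np.abs(2.0 * phase - 1.0) - 0.5)
    taps = np.floor(pos / pitch + 0.5).astype(int)
    k_max = taps.max()
    weights = np.bincount(taps + k_max, minlength=2 * k_max + 1) / n_steps
    return weights


def test_motion_kernel_static_is_identity():
    grid = pq.GridSpec.centered((20.0, 20.0, 20.0))
    k = pq.motion_kernel(pq.MotionSpec(amplitude=0.0), grid)
    assert k.shape == (1,) and k[0] == 1.0


def test_motion_kernel_matches_time_stepped_trajectory():
    grid = pq.GridSpec.centered((20.0, 20.0, 60.0))
    k = pq.motion_kernel(pq.MotionSpec(amplitude=20.0), grid)
    oracle = time_stepped_kernel(20.0, grid.voxel_size[2])
    assert k.size == oracle.size
    assert np.max(np.abs(k - oracle)) < 1e-3
    # analytic check: 9 interior taps of 0.1 plus two half-covered end taps
    assert k == pytest.approx([0.05] + [0.1] * 9 + [0.05])


@settings(deadline=None, max_examples=40)
@given(a=st.floats(min_value=0.1, max_value=60.0, allow_nan=False),
       pitch=st.floats(min_value=0.5, max_value=5.0, allow_nan=False))
def test_motion_kernel_is_a_normalized_symmetric_distribution(a, pitch):
    grid = pq.GridSpec(shape=(5, 5, 201), voxel_size=(1.0, 1.0, pitch))
    k = pq.motion_kernel(pq.MotionSpec(amplitude=a), grid)
    assert np.all(k >= 0)
    assert k.sum() == pytest.approx(1.0, abs=1e-12)
    assert k == pytest.approx(k[::-1])


def test_apply_motion_blur_identity_and_uniform_invariance():
    grid = pq.GridSpec.centered((10.0, 10.0, 40.0))
    rng = np.random.default_rng(3)
    img = pq.VoxelImage(grid=grid, values=rng.random(grid.shape))
    out = pq.apply_motion_blur(img, np.ones(1))
    assert np.array_equal(out.values, img.values)
    uniform = pq.VoxelImage(grid=grid, values=np.full(grid.shape, 2.5))
    k = pq.motion_kernel(pq.MotionSpec(amplitude=12.0), grid)
    blurred = pq.apply_motion_blur(uniform, k)
    assert blurred.values == pytest.approx(uniform.values)


def test_apply_motion_blur_matches_dense_convolution_oracle():
    """Peak of a blurred 13 mm sphere equals a direct np.convolve of each
    z-line (interior voxels, away from boundaries)."""
    body = pq.BodySpec(semi_axis_x=40.0, semi_axis_y=40.0, length=90.0)
    spec = pq.PhantomSpec(spheres=((13.0, (0.0, 0.0, 0.0)),),
                          background_activity=2.0, tbr=5.0, body=body)
    grid = pq.GridSpec.centered((100.0, 100.0, 120.0))
    img = pq.rasterize_phantom(spec, grid, supersample=2)
    k = pq.motion_kernel(pq.MotionSpec(amplitude=20.0), grid)
    blurred = pq.apply_motion_blur(img, k)
    oracle = np.apply_along_axis(lambda line: np.convolve(line, k, mode="same"),
                                 2, img.values)
    nz = grid.shape[2]
    margin = k.size
    interior = (slice(None), slice(None), slice(margin, nz - margin))
    assert blurred.values[interior] == pytest.approx(oracle[interior], abs=1e-12)
    peak_idx = grid.nearest_voxel((0.0, 0.0, 0.0))
    assert blurred.values[peak_idx] == pytest.approx(oracle[peak_idx])


def test_apply_motion_blur_rejects_bad_kernels():
    grid = pq.GridSpec(shape=(4, 4, 5), voxel_size=(1.0, 1.0, 1.0))
    img = pq.VoxelImage(grid=grid, values=np.ones(grid.shape))
    with pytest.raises(ValueError, match="normalized"):
        pq.apply_motion_blur(img, np.array([0.5, 0.6]))
    with pytest.raises(ValueError, match="longer than axis"):
        pq.apply_motion_blur(img, np.full(7, 1 / 7))


def test_apply_psf_impulse_response_is_gaussian(small_grid):
    from conftest import delta_image
    img = delta_image(shape=(41, 41, 41), voxel=(1.0, 1.0, 1.0))
    fwhm = 5.0
    out = pq.apply_psf(img, fwhm=fwhm)
    center = 20
    profile = out.values[center, center, :]
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    x = np.arange(41) - center
    expected = np.exp(-x**2 / (2 * sigma**2))
    expected /= expected.sum()
    # closed-form separable Gaussian along one axis through the peak
    line_scale = profile[center] / expected[center]
    assert profile == pytest.approx(expected * line_scale, abs=1e-6)
    # half-maximum width equals the FWHM within one voxel pitch
    above = np.nonzero(profile >= profile.max() / 2)[0]
    measured_fwhm = above[-1] - above[0] + 1.0
    assert abs(measured_fwhm - fwhm) <= 1.0


def test_apply_psf_preserves_total_activity(small_truth):
    out = pq.apply_psf(small_truth, fwhm=5.0)
    assert out.total_activity_kbq() == pytest.approx(
        small_truth.total_activity_kbq(), rel=1e-6)
    assert np.array_equal(pq.apply_psf(small_truth, fwhm=0.0).values,
                          small_truth.values)
    with pytest.raises(ValueError):
        pq.apply_psf(small_truth, fwhm=-1.0)


def test_add_noise_levels_and_determinism():
    grid = pq.GridSpec(shape=(25, 25, 16), voxel_size=(1.0, 1.0, 1.0))
    img = pq.VoxelImage(grid=grid, values=np.full(grid.shape, 10.0))
    assert np.array_equal(pq.add_noise(img, level=0.0).values, img.values)
    noisy1 = pq.add_noise(img, model="gaussian", level=0.5, seed=11)
    noisy2 = pq.add_noise(img, model="gaussian", level=0.5, seed=11)
    assert np.array_equal(noisy1.values, noisy2.values)
    # empirical SD over the 10^4-voxel region within 5% of the level
    assert noisy1.values.std() == pytest.approx(0.5, rel=0.05)
    poisson = pq.add_noise(img, model="scaled_poisson", level=0.5, seed=11)
    # scaled Poisson: variance = level * mean
    assert poisson.values.var() == pytest.approx(0.5 * 10.0, rel=0.1)
    with pytest.raises(ValueError, match="unknown noise model"):
        pq.add_noise(img, model="salt_pepper", level=0.1)


def test_activity_conserved_through_blur_and_psf(small_truth):
    """Rasterize -> motion blur -> PSF conserves total activity to 1e-3."""
    grid = small_truth.grid
    k = pq.motion_kernel(pq.MotionSpec(amplitude=30.0), grid)
    out = pq.apply_psf(pq.apply_motion_blur(small_truth, k), fwhm=5.0)
    assert out.total_activity_kbq() == pytest.approx(
        small_truth.total_activity_kbq(), rel=1e-3)


def test_static_pipeline_equals_psf_only_bit_exact(small_truth):
    static, _ = pq.simulate_acquisition(small_truth,
                                        pq.MotionSpec(amplitude=0.0),
                                        noise_level=0.0, seed=5)
    psf_only = pq.apply_psf(small_truth, fwhm=5.0)
    assert np.array_equal(static.values, psf_only.values)


def test_sphere_peak_monotone_nonincreasing_in_amplitude(small_phantom, small_truth):
    """Noise-free peak value of each sphere never increases with amplitude."""
    grid = small_truth.grid
    peaks = {d: [] for d, _ in small_phantom.spheres}
    for a in pq.DEFAULT_AMPLITUDES_MM:
        img, _ = pq.simulate_acquisition(small_truth, pq.MotionSpec(amplitude=a),
                                         noise_level=0.0, seed=0)
        for d, center in small_phantom.spheres:
            voi = pq.cubic_voi(grid.nearest_voxel(center), d / 2.0, grid)
            peaks[d].append(pq.voi_stats(img, voi).t_max)
    for d, series in peaks.items():
        assert all(a >= b - 1e-12 for a, b in zip(series, series[1:])), \
            f"peak of {d} mm sphere increased with amplitude: {series}"


def test_seeded_acquisition_is_reproducible(small_truth):
    a1, _ = pq.simulate_acquisition(small_truth, pq.MotionSpec(amplitude=10.0),
                                    noise_level=0.15, seed=99)
    a2, _ = pq.simulate_acquisition(small_truth, pq.MotionSpec(amplitude=10.0),
                                    noise_level=0.15, seed=99)
    assert np.array_equal(a1.values, a2.values)
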