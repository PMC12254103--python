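"""Acquisition emulation: motion blur, scanner PSF, and noise.

A static phantom image is degraded in three steps that stand in for a PET
acquisition of the moving phantom:

1. 1-D convolution along the superior-inferior axis with the dwell-time
   kernel of the constant-speed cyclic platform motion;
2. isotropic Gaussian smoothing emulating the reconstruction post-filter
   (5 mm FWHM by default);
3. additive noise (Gaussian, or a scaled-Poisson model with signal-dependent
   variance) standing in for post-reconstruction image noise.

Both convolutions default to reflective boundaries, which preserve total
activity exactly for symmetric kernels; the mode is recorded in the image
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import GridSpec, VoxelImage

GAUSSIAN_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class MotionSpec:
    """Cyclic 1-D platform motion along the superior-inferior axis.

    ``amplitude`` is the *total displacement range* (peak-to-peak travel) in
    mm; 0 means static.  ``speed`` and ``period`` describe the platform but do
    not enter the blur: at constant speed the positional dwell density is
    uniform over the range regardless of how fast it is traversed, so the
    kernel depends on the amplitude only.  They are kept as metadata.
    """

    amplitude: float = 0.0       # mm, peak-to-peak
    speed: float = 0.75          # cm/s, platform speed (metadata)
    period: float = 4.0          # s, nominal cycle (metadata)
    axis: int = 2                # grid axis of superior-inferior motion

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.axis not in (0, 1, 2):
            raise ValueError(f"axis must be 0, 1 or 2, got {self.axis}")


DEFAULT_AMPLITUDES_MM = (0.0, 7.0, 10.0, 20.0, 30.0)


def motion_kernel(motion: MotionSpec, grid: GridSpec) -> np.ndarray:
    """Dwell-time-weighted displacement kernel along the motion axis.

    Constant-speed back-and-forth travel over ``[-A/2, +A/2]`` with
    instantaneous turnarounds spends equal time in equal sub-intervals, so
    the continuous dwell density is uniform on the range.  Each discrete tap
    at voxel offset ``k`` receives the fraction of the range overlapping the
    voxel ``[k*p - p/2, k*p + p/2]`` where ``p`` is the axis pitch.  Weights
    are non-negative and sum to 1; ``A = 0`` yields the identity tap.
    """
    a = motion.amplitude
    if a == 0:
        return np.ones(1)
    pitch = grid.voxel_size[motion.axis]
    half = a / 2.0
    k_max = int(np.ceil((half + pitch / 2.0) / pitch))
    offsets = np.arange(-k_max, k_max + 1) * pitch
    lo = np.maximum(offsets - pitch / 2.0, -half)
    hi = np.minimum(offsets + pitch / 2.0, half)
    weights = np.clip(hi - lo, 0.0, None) / a
    nz = weights > 0
    # trim zero-weight guard taps at both ends
    first, last = np.nonzero(nz)[0][[0, -1]]
    weights = weights[first:last + 1]
    return weights / weights.sum()


def apply_motion_blur(image: VoxelImage, kernel: np.ndarray,
                      axis: int = 2, mode: str = "reflect") -> VoxelImage:
    """Convolve the image with a normalized 1-D kernel along ``axis``."""
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 1 or kernel.size < 1:
        raise ValueError("kernel must be a non-empty 1-D array")
    if not np.isclose(kernel.sum(), 1.0, atol=1e-9):
        raise ValueError(f"kernel must be normalized to sum 1, sums to {kernel.sum()}")
    if kernel.size > image.grid.shape[axis]:
        raise ValueError(
            f"kernel of {kernel.size} taps is longer than axis {axis} "
            f"({image.grid.shape[axis]} voxels)")
    if kernel.size == 1:
        return image.copy_with(image.values.copy(), boundary_mode=mode)
    blurred = ndimage.convolve1d(image.values, kernel, axis=axis, mode=mode)
    return image.copy_with(blurred, boundary_mode=mode)


def apply_psf(image: VoxelImage, fwhm: float = 5.0,
              mode: str = "reflect") -> VoxelImage:
    """Isotropic Gaussian post-filter of the given FWHM (mm)."""
    if fwhm < 0:
        raise ValueError(f"fwhm must be >= 0, got {fwhm}")
    if fwhm == 0:
        return image.copy_with(image.values.copy())
    sigma_mm = fwhm * GAUSSIAN_FWHM_TO_SIGMA
    sigma_vox = [sigma_mm / v for v in image.grid.voxel_size]
    smoothed = ndimage.gaussian_filter(image.values, sigma=sigma_vox, mode=mode)
    return image.copy_with(smoothed, psf_fwhm_mm=fwhm, boundary_mode=mode)


def add_noise(image: VoxelImage, model: str = "gaussian",
              level: float = 0.15, seed: int | None = 0) -> VoxelImage:
    """Add seeded noise to the image.

    ``gaussian`` adds i.i.d. N(0, level^2) per voxel (level in kBq/mL).
    ``scaled_poisson`` draws Poisson counts with mean ``value / level`` and
    scales back by ``level``, giving variance proportional to the signal.
    The same seed always yields a bit-identical image.
    """
    if level < 0:
        raise ValueError(f"level must be >= 0, got {level}")
    if level == 0:
        return image.copy_with(image.values.copy(), noise_model=model, noise_level=0.0)
    rng = np.random.default_rng(seed)
    if model == "gaussian":
        noisy = image.values + rng.normal(0.0, level, size=image.values.shape)
    elif model == "scaled_poisson":
        mean = np.clip(image.values, 0.0, None) / level
        noisy = rng.poisson(mean).astype(float) * level
    else:
        raise ValueError(f"unknown noise model {model!r}; "
                         "use 'gaussian' or 'scaled_poisson'")
    return image.copy_with(noisy, noise_model=model, noise_level=level,
                           noise_seed=seed)


def simulate_acquisition(phantom_image: VoxelImage, motion: MotionSpec,
                         psf_fwhm: float = 5.0, noise_model: str = "gaussian",
                         noise_level: float = 0.15, seed: int | None = 0,
                         mode: str = "reflect") -> tuple[VoxelImage, np.ndarray]:
    """Motion blur -> PSF -> noise; returns the image and the motion kernel."""
    kernel = motion_kernel(motion, phantom_image.grid)
    blurred = apply_motion_blur(phantom_image, kernel, axis=motion.axis, mode=mode)
    filtered = apply_psf(blurred, fwhm=psf_fwhm, mode=mode)
    noisy = add_noise(filtered, model=noise_model, level=noise_level, seed=seed)
    noisy.meta["motion_amplitude_mm"] = motion.amplitude
    return noisy, kernel
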