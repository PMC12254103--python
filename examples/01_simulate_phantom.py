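"""Simulate one PET acquisition of a moving NEMA-IEC-style phantom.

Builds a compact three-sphere phantom, rasterizes it with partial-volume
edge handling, applies 20 mm of superior-inferior motion blur, the 5 mm
FWHM Gaussian post-filter, and Gaussian noise, then prints how the sphere
peaks degrade.
"""

import phantomiq as pq

body = pq.BodySpec(semi_axis_x=60.0, semi_axis_y=55.0, length=100.0)
phantom = pq.PhantomSpec(
    spheres=((10.0, (25.0, 10.0, 0.0)),
             (17.0, (-25.0, 10.0, 0.0)),
             (28.0, (0.0, 32.0, 0.0))),
    background_activity=2.0,   # kBq/mL
    tbr=5.0,                   # spheres filled at 10 kBq/mL
    body=body,
)
grid = pq.GridSpec.centered((160.0, 150.0, 140.0))

truth = pq.rasterize_phantom(phantom, grid, supersample=4)
print(f"grid {grid.shape}, voxels {tuple(round(v, 3) for v in grid.voxel_size)} mm")
print(f"total activity: {truth.total_activity_kbq():.1f} kBq")

motion = pq.MotionSpec(amplitude=20.0)   # 20 mm peak-to-peak travel
acquired, kernel = pq.simulate_acquisition(truth, motion, psf_fwhm=5.0,
                                           noise_model="gaussian",
                                           noise_level=0.15, seed=42)
print(f"motion kernel: {len(kernel)} taps along z, weights sum {kernel.sum():.3f}")

for d, center in phantom.spheres:
    voi = pq.cubic_voi(grid.nearest_voxel(center), d / 2.0, grid)
    true_peak = pq.voi_stats(truth, voi).t_max
    seen_peak = pq.voi_stats(acquired, voi).t_max
    print(f"{d:4.0f} mm sphere: filled {true_peak:5.2f} kBq/mL -> "
          f"imaged peak {seen_peak:5.2f} kBq/mL")
# Smaller spheres lose more of their peak to the combined motion/PSF blur:
# that partial-volume loss is exactly what the recovery coefficient measures.
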