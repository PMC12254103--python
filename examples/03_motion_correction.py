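"""Deconvolve the known motion kernel and watch the trade-off.

The correction surrogate (Richardson-Lucy-type deconvolution of the exact
simulation kernel) restores the blurred sphere peak but amplifies the
background noise — the same contrast-versus-noise trade-off that limits
how much real data-driven motion correction helps detectability.
"""

import phantomiq as pq

body = pq.BodySpec(semi_axis_x=60.0, semi_axis_y=55.0, length=100.0)
phantom = pq.PhantomSpec(
    spheres=((13.0, (0.0, 20.0, 0.0)),),
    background_activity=2.0, tbr=5.0, body=body)
grid = pq.GridSpec.centered((160.0, 150.0, 140.0))
truth = pq.rasterize_phantom(phantom, grid, supersample=2)
static_ref = pq.apply_psf(truth, fwhm=5.0)       # motion-free reference

acq, kernel = pq.simulate_acquisition(truth, pq.MotionSpec(amplitude=20.0),
                                      noise_level=0.15, seed=7)
corrected = pq.correct_motion(acq, pq.CorrectionConfig(kernel=kernel,
                                                       iterations=25))

d, center = phantom.spheres[0]
voi = pq.cubic_voi(grid.nearest_voxel(center), d / 2.0, grid)
bg = pq.background_voi(grid, 14.0, center_mm=(0.0, -30.0, 0.0), phantom=phantom)

peak_ref = pq.voi_stats(static_ref, voi).t_max
for label, img in (("blurred", acq), ("corrected", corrected)):
    stats = pq.voi_stats(img, voi)
    b_mean, sigma_b = pq.background_stats(img, bg)
    cnr = pq.contrast_to_noise(stats.t_max, b_mean, sigma_b)
    print(f"{label:9s}: peak {stats.t_max:5.2f} kBq/mL "
          f"(static reference {peak_ref:5.2f}), "
          f"sigma_B {sigma_b:.3f} kBq/mL, CNR_max {cnr:5.1f}")
# The corrected peak moves back toward the static reference (contrast
# recovered) while sigma_B grows (noise amplified); whether CNR improves
# depends on which effect wins for this sphere size and amplitude.
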