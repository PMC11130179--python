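"""Activity versus distance from the tumor edge.

Simulates a movie whose transient amplitude is twice as large within 0.75 mm
of the tumor edge as beyond 3 mm, computes the distance-band profile, the
near/far ratio, and the circular-shuffle regression p-value, then contrasts
it with a distance-independent control.
"""

import numpy as np

from glioscope import spatial, synth, widefield

yy, xx = np.mgrid[0:40, 0:40]
mask = np.hypot(yy - 19.5, xx - 19.5) <= 4      # tumor mask, 240 um pixels
dmap = spatial.distance_map(mask, pixel_size=240.0)

spec = synth.MovieSpec(
    duration_s=240.0, frame_rate_hz=10.0, fov_shape=(40, 40), pixel_size=240.0,
    baseline_noise_sd=1.0, event_rate=0.1, amplitude=5.0, event_duration_s=1.0,
    distance_gradient=synth.DistanceGradient(factor=2.0), seed=5)
movie, _, _ = synth.generate_movie(spec, tumor_mask=mask)
metrics = widefield.compute_pixel_metrics(movie)

profile = spatial.band_profile(metrics.mean_amplitude, dmap)
print("amplitude by 0.75-mm distance band:")
print(profile[["band_index", "distance_lo_um", "n_pixels", "mean"]]
      .to_string(index=False))

ratio = spatial.near_far_ratio(metrics.mean_amplitude, dmap)
print(f"\nnear/far amplitude ratio: {ratio.ratio:.2f} (planted factor 2.0; "
      f"{ratio.n_near} near px, {ratio.n_far} far px)")

m, d = spatial.raster_vectors(metrics.mean_amplitude, dmap)
res = spatial.shuffle_regression(m, d, n_shuffles=9999, seed=0)
print(f"distance regression: adjusted R^2 = {res.observed_adjusted_r2:.3f}, "
      f"circular-shuffle p = {res.p_value:.4f} "
      f"(corrected {res.p_value_corrected:.4f})")

# control: no planted gradient -> ratio near 1, p not small
spec_null = synth.MovieSpec(
    duration_s=240.0, frame_rate_hz=10.0, fov_shape=(40, 40), pixel_size=240.0,
    baseline_noise_sd=1.0, event_rate=0.1, amplitude=5.0, event_duration_s=1.0,
    seed=6)
movie0, _, _ = synth.generate_movie(spec_null)
metrics0 = widefield.compute_pixel_metrics(movie0)
m0, d0 = spatial.raster_vectors(metrics0.mean_amplitude, dmap)
res0 = spatial.shuffle_regression(m0, d0, n_shuffles=9999, seed=0)
r0 = spatial.near_far_ratio(metrics0.mean_amplitude, dmap)
print(f"\ncontrol (no gradient): ratio {r0.ratio:.2f}, shuffle p = {res0.p_value:.3f}")
print("A small p only where a gradient was planted shows the null is calibrated.")
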