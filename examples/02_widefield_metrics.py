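"""Quiet-wakefulness gating and per-pixel calcium event metrics.

Simulates a mesoscale dF/F movie with Poisson transients (0.1 events/s,
amplitude 5x the noise SD, 1 s duration) together with wheel and whisker
signals containing planted running/whisking bouts, gates the movie to 300 s
of quiet wakefulness, and prints how well the four activity metrics recover
the planted parameters.
"""

import numpy as np

from glioscope import synth, widefield

fs = 10.0
movie_spec = synth.MovieSpec(
    duration_s=340.0, frame_rate_hz=fs, fov_shape=(30, 30), pixel_size=240.0,
    baseline_noise_sd=1.0, event_rate=0.1, amplitude=5.0, event_duration_s=1.0,
    seed=2)
movie, catalog, truth = synth.generate_movie(movie_spec)

behavior = synth.generate_behavior(synth.BehaviorSpec(
    duration_s=340.0, sample_rate_hz=fs,
    run_bouts=[(30.0, 45.0, 0.06)], whisk_bouts=[(90.0, 105.0, 1.0)], seed=3))

quiet = widefield.detect_quiet_epochs(behavior)
print(f"quiet wakefulness: {quiet.total_quiet_s:.0f} s available, "
      f"{quiet.selected.sum() / fs:.0f} s selected (earliest frames)")

metrics = widefield.compute_pixel_metrics(movie, quiet)
print(f"planted events: {len(catalog)} across 900 pixels\n")
print("metric             planted    recovered (median over pixels)")
rows = [("events_per_sec", 0.1), ("mean_amplitude", 5.0), ("mean_duration", 1.0)]
for name, planted in rows:
    got = float(np.nanmedian(metrics.metric(name)))
    print(f"{name:18s} {planted:8.3g}   {got:8.3g}  ({(got - planted) / planted:+.1%})")
act = float(np.nanmedian(metrics.activity_per_min))
act_truth = float(np.nanmedian(truth["mean_signal"] * fs * 60))
print(f"{'activity_per_min':18s} {act_truth:8.3g}   {act:8.3g}"
      f"  ({(act - act_truth) / act_truth:+.1%})")
print("\nEach value is the per-pixel metric's median; recovery within ~10%"
      "\nis the pipeline's working accuracy at this SNR.")
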