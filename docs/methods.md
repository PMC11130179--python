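# Methods

This note documents the models, estimators and numerical choices behind
`glioscope`, what the synthetic-data generators do and do not emulate, and
the known limitations.

## Tumor dynamics

**CV/day.** Serial snapshots from one animal are first scaled by the
animal's grand-mean intensity across sessions (removing lamp/exposure drift
without affecting the statistic, which is scale-free). The later image is
divided by the earlier pixel-wise over a validity mask; pixels whose
denominator falls below 1% of the image mean are excluded (the ratio is
undefined there, matching vasculature-masking practice). CV/day is the
population SD (divide by N) of the ratio image over valid pixels, divided by
its mean and by the day gap. Population SD is chosen over sample SD because
the pixels are the full population of the ratio image, and it makes the
two-pixel worked example ([1,1] vs [1,3] over 2 days → 0.25) exact. A
per-pixel temporal variant (CV of each pixel across sessions, averaged) is
exposed separately as `cv_per_day_pixelwise`; the ratio-image form is the
primary statistic.

**Segmentation.** The tumor-mask rule is a design choice here: Otsu's
threshold on log-intensity gives a rough foreground, then the final mask is
the half-maximum level between the foreground and background medians,
keeping the largest connected component with holes filled. On synthetic
discs with a 2-pixel sigmoid edge this recovers area to well within one
perimeter-length of pixels, which is the natural discretization bound for
any contour-based area estimate. An image with no separable foreground
returns an explicit empty-mask result (area 0), not an exception.

**Expansion classification.** `fast` is strictly above 1e5 um^2/day; the
signed rate is compared directly (a shrinking tumor is `slow`).

**Percentile time course.** Intervals are assigned to 10-day bins over
P45-P135 by their midpoint day; the per-(animal, bin) 90th percentile uses
linear interpolation (numpy's default), so values 1..10 give 9.1.

## Widefield activity

**Gating.** Frames with wheel speed above 0.043 m/s are excluded. The
whisking index is the per-frame mean absolute frame difference over the
whisker ROI; its per-recording threshold is Otsu's split of the index
histogram, accepted only when the high-motion mode is separated from the
index median by more than 4 robust SDs — a recording without whisking then
excludes nothing, instead of Otsu splitting pure noise in half. When more
than 300 s of quiet remain, the earliest frames are used (determinism).
Less than 300 s yields an explicit insufficient-data result; metric
computation on it raises.

**Noise estimate.** Per pixel, sigma = 1.4826 x MAD of the trace after
subtracting a ~10 s running-median baseline (computed on ~2 s blocks for
speed). MAD is insensitive to the events themselves.

**Event detection.** The trace is smoothed with a 0.5 s boxcar (long enough
to suppress single-frame noise, short relative to second-scale transients),
and events are maximal runs of the smoothed trace above median + k*SD
(k = 3). Runs shorter than 2 frames are discarded and runs separated by
fewer than 2 frames merged (flicker suppression). Boundaries are then
refined on the raw trace, so a noiseless rectangular pulse is recovered at
exactly its own width. Because transient arrivals are Poisson, a few percent
of events overlap and would otherwise merge into one run; within each run, a
short-difference onset signal (mean of the next 0.2 s minus mean of the
previous 0.2 s, which peaks at the rise height at every instantaneous onset
regardless of overlap) is scanned for additional onset-sized peaks
(height > k and prominence > 2 noise SDs of the difference), and the run is
split there. Event amplitude is the smoothed peak relative to the pre-event
level — for isolated events the pre-event level is the trace median, so this
equals the absolute dF/F peak on baseline-normalized traces; for a split
event it is the level just before its onset, which keeps a transient riding
on another from double-counting the first one's amplitude.

One caveat follows from splitting: events/s is monotone nonincreasing in k
for separated transients, but when transients overlap the very notion of
"number of events" is threshold-dependent and strict monotonicity can fail;
the property is therefore only claimed (and tested) for separated events.

**Metrics.** activity_per_min is the integrated dF/F per minute
(trace mean x frames per minute); events_per_sec divides the event count by
the 300 s analysis window; amplitude and duration are per-event means
(NaN where a pixel has no events). At the working SNR of the synthetic
movies (amplitude 5x noise SD) the systematic recovery errors are about
-7% on rate (unresolvable sub-0.5 s overlaps), +6% on amplitude (noise
maxima), and under 1% on duration and activity.

## Spatial analysis

Distances are the Euclidean distance transform from the tumor-edge pixel
set, in um; tumor-interior pixels get distance 0 and are excluded from all
extramarginal statistics. Bands are 0.75 mm wide; the near/far ratio is the
mean metric at 0 < d < 0.75 mm over the mean at d > 3 mm, flagged undefined
(never silently dropped) when either set is empty.

The circular-shuffle regression tests a metric-distance relation per
recording. Pixels are ordered by a fixed raster scan of the extramarginal
mask; each shuffle rotates the distance vector by a uniform offset in
[1, N-1], approximately preserving spatial autocorrelation, which is the
point of circular rather than free permutation. Since rotation changes only
the cross-covariance, the R^2 of every one of the N rotations is obtained
from a single FFT cross-correlation, and shuffles are draws from those
offsets — 500,000 shuffles cost milliseconds and are exactly reproducible
from the seed. The p-value counts shuffles with strictly higher adjusted R^2
(adjusted R^2 = 1 - (1 - R^2)(N-1)/(N-2) for the single predictor; it is
monotone in R^2 at fixed N, so the comparison is done on R^2). The minimum
reportable p is 0; the (count+1)/(N+1) corrected value is also reported. A
zero-variance metric gives R^2 = 0 and p = 1 by convention. The regression
is run per recording and per metric; on white-noise nulls the empirical
type-I rate at 0.05 is ~0.055 and the p distribution is uniform by KS test.

## Cellular ensembles

**Deconvolution.** Nonnegative AR(1) inversion by an online
pool-adjacent-violators pass (OASIS-style), minimizing
1/2||c - y||^2 + lambda*sum(s) subject to s_t = c_t - gamma*c_{t-1} >= 0.
lambda defaults to the noise SD; with lambda = 0 the inversion is exact and
recovers the spike support of noiseless traces exactly. gamma defaults to
exp(-1/(frame_rate * 1 s)) for a 1 s indicator decay.

**Event extraction.** The noise floor is median + 3 SD of the values at or
below the trace's 20th percentile. That rule presumes dense residual noise
in the deconvolved trace; an L1-penalized inversion instead compresses
sub-noise mass to exactly zero, making the bottom quintile degenerate
(SD 0). In that case the residual noise appears as a low mode of small
positive bins, and the floor falls back to an Otsu split of the log positive
values, accepted only when the two modes are more than 4x apart — a clean
trace (one mode) then keeps every positive bin as a spike. Both rules are
homogeneous in the data, so doubling the trace doubles amplitudes and leaves
event counts unchanged.

**Network and clusters.** Pairwise Pearson correlations on quiet frames,
negatives clipped to 0 (the cohesiveness objective and the weighted CC need
nonnegative weights), diagonal 0. Cluster detection grows candidate groups
from unclaimed seeds in decreasing weighted-degree order, adding or removing
one node per step while the cohesiveness
W_in / (W_in + W_bound + penalty*|V|) increases (penalty 2); candidates with
pairwise match coefficient |A∩B|^2/(|A||B|) >= 0.8 are merged, and groups
below 3 members or mean pairwise density 0.3 are discarded. Parameters are
the reference algorithm's published defaults and are all exposed. On random
graphs with n <= 8 the greedy search attains the exhaustive
best-cohesiveness subset in every tested instance; this is verified in the
test suite, not guaranteed in general.

**Clustering coefficient.** Onnela form with weights normalized by the
network maximum; CC_i = (W^(1/3))^3_ii / (k_i(k_i-1)) with k_i the count of
nonzero-weight neighbors, 0 when k_i < 2. It reduces to the unweighted
transitivity-based CC when all nonzero weights are equal and matches
exhaustive triangle enumeration to 1e-12. The full weighted graph is used
(no edge thresholding).

**Group assembly.** Two-stage seeded sampling: within a group, each
recording contributes the size of the group's smallest recording (equal
animal weighting), then 150 (location comparisons) or 200 (time-course
comparisons) neurons are drawn from the pool without replacement; a pool
smaller than the request is used whole, with a warning.

## Statistics

Rank-sum: exact enumeration of all C(n+m, n) rank assignments (midranks for
ties) when n + m <= 12, two-tailed p = 2*min(P(W <= w), P(W >= w)) capped at
1; otherwise the tie-corrected normal approximation with continuity
correction (the two branches agree within 0.02 at n = m = 6). Kruskal-Wallis
uses the tie-corrected H; pairwise follow-ups are rank-sum tests judged at
alpha / (number of pairs) (Dunn-style z tests on pooled ranks are available
as an option). The Bonferroni family is one figure-panel-like family — all
pairwise comparisons within one metric's group table; empirical family-wise
type-I error over 1000 null simulations is ~0.03 at alpha = 0.05.

## Synthetic data: what it emulates and what it does not

* Tumor series: a disc with a smooth sigmoid edge (2 px wide) and smooth
  angular margin jitter, with piecewise-linear area growth. The half-maximum
  contour defines the ground-truth mask. No real margin texture, no depth
  structure, no vascular shadowing.
* Movies: per-pixel Poisson-timed transients with instantaneous rise, a
  plateau of the stated duration, and a 0.1 s exponential tail, summing
  linearly when they overlap, plus white Gaussian noise. The plateau (rather
  than a pure exponential of the stated time constant) is what makes the
  planted duration the quantity a threshold-crossing detector measures; a
  pure exponential would make "duration" threshold-relative and
  unrecoverable. The optional distance gradient scales amplitude as a
  geometric ramp between a near plateau (< 0.75 mm, factor x base) and a far
  plateau (> 3 mm, base), so the planted factor is exactly the near/far
  band-mean ratio. No hemodynamics, no optics/PSF, no motion, no shared
  spatial background activity.
* Behavior: velocity exactly equals bout speeds; whisker ROI pixels are
  white noise with elevated SD during whisk bouts. Real wheel and whisker
  signals are smoother and autocorrelated.
* Populations: cluster members co-fire on shared Poisson event times with a
  stated probability, on top of independent background spikes, convolved
  with an AR(1) kernel. No spatially structured noise, no neuropil
  contamination (traces are assumed corrected upstream).

Passing recovery tests on these inputs validates the estimators'
correctness and calibration under the stated generative model; it does not
certify performance on real data with motion residue, hemodynamic artifacts
or correlated noise, which are explicitly out of scope.

## Problem sizes and defaults

The bundled demo cohort and the reproduction script use desk-scale sizes
chosen to exercise every code path with comfortable statistics: 2 genotypes
x 3 animals x 6 sessions, 30x30-pixel movies at 5 Hz (340 s each, 300 s of
quiet analyzed), a 50x50x3000-frame movie for metric recovery, 200 null
recordings x 999 shuffles for permutation calibration (the per-recording
default for real analyses is 500,000 shuffles), 100 neurons for
deconvolution checks, and 1000 simulations for test calibration. All
physical defaults (0.043 m/s, 3 SD, 0.75 mm, 3 mm, 1e5 um^2/day, 10-day
bins over P45-135, 90th percentile, time bins P41-49/P50-56/P70-99, 150/200
subsample sizes) live in `glioscope.defaults`.

## Known limitations

* Whisking thresholds rely on bimodality of the motion index; gradual,
  continuous whisking would not separate cleanly.
* The onset-splitting step cannot resolve transients closer than ~0.4 s at
  10 Hz; the residual rate bias (~-5%) is inherent to threshold detection
  of overlapping events.
* Greedy cohesiveness optimization has no global-optimality guarantee on
  large graphs; overlap-merging is transitive and can chain.
* The circular-shift null preserves autocorrelation only approximately on a
  raster-flattened 2-D field.
* Glutamate snapshots are treated identically to calcium snapshots (the
  pipeline has no glutamate-specific generative model or kinetics).
* No mixed-effects modeling: neurons and recordings are pooled with equal
  per-recording subsampling, as in the comparison design the pipeline
  mirrors.
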