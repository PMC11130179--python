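"""Analysis defaults shared across the pipeline.

All thresholds that define the analysis live here so that every stage and the
pipeline runner draw from a single documented block.  Units are stated per
constant.  Overriding any of these is done per-call (every operation takes the
relevant value as a keyword argument) or through the pipeline config.
"""

#: Wheel-speed threshold (m/s) above which a frame counts as active running
#: and is excluded from quiet wakefulness.
RUN_SPEED_THRESHOLD_M_S = 0.043

#: Seconds of quiet wakefulness required before mesoscale metrics are computed.
QUIET_REQUIRED_S = 300.0

#: Event detection threshold: median + K_SD * (robust noise SD).
EVENT_K_SD = 3.0

#: Spatial downsampling factor for widefield movies (block mean).
DOWNSAMPLE_FACTOR = 8

#: Width of tumor-distance bands (um).
BAND_WIDTH_UM = 750.0

#: Pixels farther than this from the tumor edge form the "far" reference set (um).
FAR_MIN_UM = 3000.0

#: Local tumor expansion rate (um^2/day) separating slow from fast phases;
#: fast is strictly above this value.
FAST_EXPANSION_UM2_PER_DAY = 1e5

#: Number of circular shuffles for the distance-regression permutation null.
N_SHUFFLES = 500_000

#: Postnatal-day time bins for cellular-resolution recordings (inclusive).
TIME_BINS = {"early": (41, 49), "mid": (50, 56), "late": (70, 99)}

#: Per-group subsample sizes for pooled cellular comparisons
#: (intra/extramarginal comparisons use 150, time-course comparisons use 200).
SUBSAMPLE_INTRAMARGINAL = 150
SUBSAMPLE_TIMECOURSE = 200

#: CV/day time-course summary: bin width (days), postnatal-day range, percentile.
PERCENTILE_BIN_DAYS = 10
PERCENTILE_DAY_RANGE = (45, 135)
PERCENTILE_Q = 90.0

#: ClusterONE-style cluster detection parameters (reference defaults).
CLUSTER_MIN_SIZE = 3
CLUSTER_PENALTY = 2.0
CLUSTER_DENSITY_THRESHOLD = 0.3
CLUSTER_OVERLAP_THRESHOLD = 0.8

#: Family-wise significance level before Bonferroni correction.
ALPHA = 0.05
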