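# glioscope

Analysis pipeline for chronic in-vivo imaging of cortical glioma and the
surrounding neural activity, with a synthetic-data module that plants ground
truth for every stage so the whole pipeline can be validated by parameter
recovery.

## Who this is for

Labs following tumor-bearing mouse cortex over weeks with widefield
(mesoscale) and two-photon (cellular) fluorescence imaging face a chain of
bespoke quantification steps: how fast is the tumor infiltrating and
expanding, how does ongoing calcium activity change with distance from the
tumor edge and with the tumor's concurrent growth phase, and how does the
functional organization of neuronal ensembles near the margin evolve?
`glioscope` implements that chain as a tested Python library. The raw animal
data such studies produce are typically restricted, so every input the
pipeline consumes can also be simulated with known parameters.

## The statistics at the core

**Tumor infiltration (CV/day).** For serial tumor-fluorescence snapshots
$I_1, I_2$ taken $d$ days apart, the ratio image $R = I_2 / I_1$ is formed
over valid pixels and

$$\mathrm{CV/day} = \frac{\sigma(R)}{\mu(R)\,d}$$

with population SD over pixels. The statistic is invariant to global
brightness changes but responds to any spatial redistribution of tumor
fluorescence — infiltration, motility, morphology change. Time courses are
summarized as per-animal 90th percentiles in 10-day bins (P45–P135).

**Expansion rate.** Segmented tumor area difference per day
($\mu m^2$/day), classified *slow* ($\le 10^5$) or *fast* ($> 10^5$).

**Mesoscale event metrics.** On 300 s of quiet wakefulness (wheel speed
$\le$ 0.043 m/s, no whisking), each pixel's ΔF/F trace is scanned for
calcium events by thresholding at median + 3 SD (robust MAD-based noise
estimate); four metrics follow: activity per minute, events/s, mean event
amplitude, mean event duration.

**Distance-band analysis.** Euclidean distance from the tumor edge in
0.75-mm bands; the near/far ratio divides the mean metric within 0.75 mm by
the mean beyond 3 mm. Significance of a metric-distance regression comes
from a circular-shuffle permutation null: distances are rotated along the
raster order of extramarginal pixels (500,000 shuffles by default) and
$p$ is the fraction of shuffles whose adjusted $R^2$ exceeds the observed.

**Cellular ensembles.** Nonnegative AR(1) deconvolution (OASIS-style
pool-adjacent-violators), per-neuron event metrics with a
bottom-20th-percentile noise floor, Pearson correlation networks, overlapping
cluster detection by greedy cohesiveness optimization
$f(V) = W_{in}/(W_{in} + W_{bound} + p\,|V|)$ with minimum size 3, and the
Onnela weighted clustering coefficient
$CC_i = \sum_{j,k}(\hat w_{ij}\hat w_{jk}\hat w_{ik})^{1/3} / k_i(k_i-1)$.

**Group comparisons.** Two-tailed Wilcoxon rank-sum (exact enumeration for
$n+m \le 12$) and Kruskal–Wallis with Bonferroni-corrected pairwise
follow-ups.

## Worked example

`examples/` holds one short script per capability. For instance,
`python examples/01_tumor_expansion.py` simulates a tumor growing at
3×10⁴ µm²/day that accelerates to 2×10⁵ µm²/day and prints:

```
interval   CV/day   rate (um^2/day)   class   planted rate
P50-P54    0.096       2.99e+04      slow         3e+04
P54-P58    0.093       3.04e+04      slow         3e+04
P58-P62    0.293       1.16e+05      fast      1.15e+05
P62-P66    0.402       1.98e+05      fast         2e+05
```

Each interval's expansion rate is recovered from segmented snapshot areas
(the P58–P62 interval straddles the planted acceleration, hence the
intermediate rate), and the slow/fast classification flips exactly where the
growth schedule crosses 10⁵ µm²/day. `python examples/02_widefield_metrics.py`
gates a movie to 300 s of quiet wakefulness and recovers planted event rate,
amplitude, and duration to within ~7%; `03_distance_bands.py` recovers a
planted near/far amplitude gradient (ratio 1.90 vs planted 2.0) with a
circular-shuffle p of 0.0000 versus 0.707 for a gradient-free control;
`04_ensembles.py` recovers three planted coactivation clusters with Jaccard
1.0; `05_full_cohort.py` runs the full pipeline end to end.

A thin CLI wraps the pipeline runner: `glioscope run --seed 1 --out outdir`.

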