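"""Synthetic cohort generator with planted ground truth.

Every input the analysis consumes can be generated here: serial tumor
snapshots with a piecewise-linear planted area schedule, widefield dF/F
movies with Poisson-timed transients (optionally graded by distance from the
tumor edge), behavior traces with running/whisking bouts, and cellular
populations with AR(1)-kernel calcium transients organized into planted
co-activation clusters.  All generators are pure functions of their spec and
seed, and return the planted ground truth alongside the data so downstream
stages can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ActivityMovie, BehaviorTrace, SessionImage

__all__ = [
    "TumorGrowthSpec",
    "MovieSpec",
    "DistanceGradient",
    "PopulationSpec",
    "BehaviorSpec",
    "generate_tumor_series",
    "generate_movie",
    "generate_population",
    "generate_behavior",
]


# --------------------------------------------------------------------------
# tumor snapshot series
# --------------------------------------------------------------------------

@dataclass
class TumorGrowthSpec:
    """Planted radial tumor growth across imaging sessions.

    The tumor is a bright disc whose *area* grows piecewise-linearly:
    ``area_slope_per_phase`` lists ``((day_lo, day_hi), slope_um2_per_day)``
    segments.  The rendered margin has a smooth angular jitter with standard
    deviation ``margin_jitter_sd`` (um) so segmentation is nontrivial; the
    ground-truth mask is defined at the half-maximum intensity contour.
    """

    center: tuple[float, float]               # (y, x) in um
    initial_radius: float                     # um, at the first session day
    area_slope_per_phase: list                # [((day_lo, day_hi), um2/day), ...]
    session_days: list                        # strictly increasing postnatal days
    pixel_size: float                         # um
    fov_shape: tuple[int, int]                # (rows, cols)
    margin_jitter_sd: float = 0.0             # um
    edge_width_px: float = 2.0                # sigmoid 10-90% width, pixels
    background_level: float = 0.05
    background_noise_sd: float = 0.01
    intensity_fluctuation_sd: float = 0.0     # per-session smooth multiplicative field
    session_gains: list | None = None         # optional per-session brightness scale

    def __post_init__(self) -> None:
        if self.initial_radius < 0:
            raise ValueError("initial_radius must be nonnegative")
        days = list(self.session_days)
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("session_days must be strictly increasing")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.session_gains is not None and len(self.session_gains) != len(days):
            raise ValueError("session_gains must match session_days")
        # FOV containment at every session (with jitter headroom)
        for day in days:
            r = np.sqrt(self.area_at(day) / np.pi) + 3.0 * self.margin_jitter_sd
            cy, cx = self.center
            h = self.fov_shape[0] * self.pixel_size
            w = self.fov_shape[1] * self.pixel_size
            if cy - r < 0 or cx - r < 0 or cy + r > h or cx + r > w:
                raise ValueError(
                    f"tumor exceeds FOV on day {day} (radius {r:.0f} um)"
                )

    def area_at(self, day: float) -> float:
        """Planted tumor area (um^2) on a given postnatal day."""
        area = np.pi * self.initial_radius ** 2
        d0 = self.session_days[0]
        for (lo, hi), slope in self.area_slope_per_phase:
            overlap = max(0.0, min(float(day), float(hi)) - max(float(d0), float(lo)))
            area += slope * overlap
        return max(area, 0.0)


def _angular_jitter(rng: np.random.Generator, sd: float, n_modes: int = 6):
    """Smooth periodic radius perturbation r(theta) with stated SD."""
    if sd <= 0:
        return lambda theta: np.zeros_like(theta)
    amps = rng.normal(size=n_modes)
    phases = rng.uniform(0, 2 * np.pi, size=n_modes)
    norm = sd / np.sqrt(0.5 * np.sum(amps ** 2)) if np.any(amps) else 0.0

    def jitter(theta):
        out = np.zeros_like(theta)
        for k in range(n_modes):
            out += amps[k] * np.cos((k + 1) * theta + phases[k])
        return norm * 0.5 * out  # cos modes have var 1/2 each

    return jitter


def generate_tumor_series(spec: TumorGrowthSpec, seed: int = 0):
    """Render one snapshot per session plus ground-truth masks and areas.

    Returns
    -------
    images : list of SessionImage (channel "tumor")
    truth : dict with "masks" (list of bool grids at half-maximum),
        "areas" (um^2, from the masks), "target_areas" (analytic schedule).
    """
    rng = np.random.default_rng(seed)
    ny, nx = spec.fov_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    y_um = (yy + 0.5) * spec.pixel_size
    x_um = (xx + 0.5) * spec.pixel_size
    cy, cx = spec.center
    r_um = np.hypot(y_um - cy, x_um - cx)
    theta = np.arctan2(y_um - cy, x_um - cx)
    edge_scale = spec.edge_width_px * spec.pixel_size / 4.394  # 10-90% width -> logistic scale

    images, masks, areas, target_areas = [], [], [], []
    for i, day in enumerate(spec.session_days):
        area = spec.area_at(day)
        radius = np.sqrt(area / np.pi)
        jit = _angular_jitter(rng, spec.margin_jitter_sd)
        local_r = radius + jit(theta)
        profile = 1.0 / (1.0 + np.exp((r_um - local_r) / max(edge_scale, 1e-9)))
        img = spec.background_level + profile
        if spec.intensity_fluctuation_sd > 0:
            from scipy.ndimage import gaussian_filter

            f = rng.normal(0.0, 1.0, size=(ny, nx))
            f = gaussian_filter(f, sigma=max(2.0, min(ny, nx) / 16))
            f *= spec.intensity_fluctuation_sd / max(f.std(), 1e-12)
            img = img * (1.0 + f)
        img = img + rng.normal(0.0, spec.background_noise_sd, size=(ny, nx))
        img = np.clip(img, 0.0, None)
        gain = 1.0 if spec.session_gains is None else float(spec.session_gains[i])
        img = img * gain
        mask = profile >= 0.5
        images.append(
            SessionImage(pixels=img, pixel_size=spec.pixel_size, day=int(day),
                         channel="tumor")
        )
        masks.append(mask)
        areas.append(float(mask.sum()) * spec.pixel_size ** 2)
        target_areas.append(area)

    return images, {"masks": masks, "areas": areas, "target_areas": target_areas}


# --------------------------------------------------------------------------
# widefield movies
# --------------------------------------------------------------------------

@dataclass
class DistanceGradient:
    """Planted near/far modulation of transient amplitude.

    The amplitude map is a geometric ramp between two plateaus: ``factor`` x
    the base amplitude for pixels closer than ``near_um`` to the tumor edge,
    the base amplitude beyond ``far_um``, and an exponential-in-distance
    interpolation in between.  With the default anchors the planted near/far
    band-mean ratio equals ``factor`` exactly.
    """

    factor: float = 2.0
    near_um: float = 750.0
    far_um: float = 3000.0

    def profile(self, distance_um: np.ndarray) -> np.ndarray:
        t = np.clip((distance_um - self.near_um) / (self.far_um - self.near_um), 0.0, 1.0)
        return self.factor ** (1.0 - t)


@dataclass
class MovieSpec:
    """Planted per-pixel Poisson transient model for a dF/F movie.

    Transients are boxcar-with-decay: an instantaneous rise to the planted
    amplitude, a plateau of ``event_duration_s``, then an exponential tail
    with time constant ``decay_tau_s``.  Overlapping events sum linearly.
    """

    duration_s: float
    frame_rate_hz: float
    fov_shape: tuple[int, int]
    pixel_size: float                       # um
    baseline_noise_sd: float                # dF/F units
    event_rate: float | np.ndarray          # events/s, scalar or per-pixel map
    amplitude: float | np.ndarray           # dF/F, scalar or per-pixel map
    event_duration_s: float
    decay_tau_s: float = 0.1
    distance_gradient: DistanceGradient | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("duration and frame rate must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if np.any(np.asarray(self.event_rate) < 0):
            raise ValueError("event rates must be nonnegative")
        if np.any(np.asarray(self.amplitude) < 0):
            raise ValueError("amplitudes must be nonnegative")
        if self.event_duration_s <= 0:
            raise ValueError("event_duration_s must be positive")
        if self.baseline_noise_sd < 0:
            raise ValueError("baseline_noise_sd must be nonnegative")


def _as_map(value, shape) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(shape, float(arr))
    if arr.shape != tuple(shape):
        raise ValueError(f"map shape {arr.shape} does not match FOV {shape}")
    return arr


def generate_movie(spec: MovieSpec, tumor_mask: np.ndarray | None = None):
    """Simulate a dF/F movie plus the complete planted event catalog.

    If ``spec.distance_gradient`` is set, ``tumor_mask`` is required and the
    amplitude map is modulated by distance from the tumor edge; pixels inside
    the tumor mask are excluded from the movie's validity mask.

    Returns
    -------
    movie : ActivityMovie
    catalog : DataFrame with columns (y, x, onset_frame, amplitude, duration_s)
    truth : dict with "rate_map", "amplitude_map", "mean_signal"
        (the noiseless temporal mean per pixel) and "duration_s".
    """
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.fov_shape
    rate_map = _as_map(spec.event_rate, (ny, nx))
    amp_map = _as_map(spec.amplitude, (ny, nx))
    valid = np.ones((ny, nx), dtype=bool)

    if spec.distance_gradient is not None:
        if tumor_mask is None:
            raise ValueError("distance_gradient requires a tumor_mask")
        from .spatial import distance_map

        dmap = distance_map(tumor_mask, spec.pixel_size)
        amp_map = amp_map * spec.distance_gradient.profile(dmap.distance)
        valid &= ~np.asarray(tumor_mask, dtype=bool)

    n_frames = int(round(spec.duration_s * spec.frame_rate_hz))
    fs = spec.frame_rate_hz
    plateau = max(1, int(round(spec.event_duration_s * fs)))
    tail = int(np.ceil(5.0 * spec.decay_tau_s * fs))
    kernel = np.ones(plateau + tail)
    if tail:
        kernel[plateau:] = np.exp(-np.arange(1, tail + 1) / (spec.decay_tau_s * fs))

    signal = np.zeros((n_frames, ny, nx), dtype=np.float32)
    counts = rng.poisson(rate_map * spec.duration_s)
    ys, xs = np.nonzero(counts)
    rows = []
    for y, x in zip(ys, xs):
        k = counts[y, x]
        onsets = np.sort(rng.integers(0, n_frames, size=k))
        amp = amp_map[y, x]
        for t0 in onsets:
            seg = kernel[: n_frames - t0]
            signal[t0:t0 + len(seg), y, x] += amp * seg
            rows.append((y, x, int(t0), float(amp), spec.event_duration_s))
    catalog = pd.DataFrame(rows, columns=["y", "x", "onset_frame", "amplitude",
                                          "duration_s"])
    mean_signal = signal.mean(axis=0).astype(float)
    dff = signal + rng.normal(0.0, spec.baseline_noise_sd,
                              size=signal.shape).astype(np.float32)
    movie = ActivityMovie(dff=dff, frame_rate=fs, pixel_size=spec.pixel_size,
                          valid_mask=valid)
    truth = {"rate_map": rate_map, "amplitude_map": amp_map,
             "mean_signal": mean_signal, "duration_s": spec.event_duration_s}
    return movie, catalog, truth


# --------------------------------------------------------------------------
# cellular populations
# --------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """Planted neuronal population with co-activation clusters.

    Cluster events arrive as a Poisson process (``cluster_event_rate_hz``);
    each member of a cluster fires at each of its cluster's events with
    probability ``within_cluster_coactivation_prob``.  All neurons also fire
    independent background spikes at ``background_rate``.  Spikes are
    convolved with an AR(1) kernel (decay ``ar_decay`` per frame), scaled by
    ``transient_amplitude``, and Gaussian noise is added.
    """

    n_neurons: int
    n_clusters: int
    cluster_sizes: list
    within_cluster_coactivation_prob: float
    background_rate: float                  # events/s per neuron
    ar_decay: float                         # gamma per frame, 0 < gamma < 1
    transient_amplitude: float
    noise_sd: float
    frame_rate_hz: float
    duration_s: float
    cluster_event_rate_hz: float = 0.2
    neuron_positions: np.ndarray | None = None   # N x 2 (y, x) um
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cluster_sizes) != self.n_clusters:
            raise ValueError("cluster_sizes must have n_clusters entries")
        if sum(self.cluster_sizes) > self.n_neurons:
            raise ValueError("sum of cluster_sizes cannot exceed n_neurons")
        if not (0.0 < self.ar_decay < 1.0):
            raise ValueError("ar_decay must be in (0, 1)")
        if not (0.0 <= self.within_cluster_coactivation_prob <= 1.0):
            raise ValueError("coactivation probability must be in [0, 1]")
        if self.background_rate < 0 or self.cluster_event_rate_hz < 0:
            raise ValueError("rates must be nonnegative")


def _ar1_filter(spikes: np.ndarray, gamma: float) -> np.ndarray:
    """Convolve spike rows with the causal AR(1) kernel gamma**t."""
    from scipy.signal import lfilter

    return lfilter([1.0], [1.0, -gamma], spikes, axis=-1)


def generate_population(spec: PopulationSpec):
    """Simulate dF/F traces plus ground-truth spikes and cluster memberships.

    Returns
    -------
    dff : N x T array
    spikes : N x T array (planted spike indicator, pre-convolution)
    memberships : list of sets of neuron indices (planted clusters)
    positions : N x 2 array of (y, x) um
    """
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration_s * spec.frame_rate_hz))
    n = spec.n_neurons
    spikes = np.zeros((n, n_frames))

    # background spikes for everyone
    p_bg = spec.background_rate / spec.frame_rate_hz
    if p_bg > 0:
        spikes += rng.random((n, n_frames)) < p_bg

    memberships, start = [], 0
    for size in spec.cluster_sizes:
        members = list(range(start, start + size))
        start += size
        n_events = rng.poisson(spec.cluster_event_rate_hz * spec.duration_s)
        event_frames = rng.integers(0, n_frames, size=n_events)
        for t in event_frames:
            fire = rng.random(size) < spec.within_cluster_coactivation_prob
            spikes[np.asarray(members, dtype=int)[fire], t] += 1
        memberships.append(set(members))

    calcium = _ar1_filter(spikes, spec.ar_decay) * spec.transient_amplitude
    dff = calcium + rng.normal(0.0, spec.noise_sd, size=calcium.shape)

    if spec.neuron_positions is not None:
        positions = np.asarray(spec.neuron_positions, dtype=float)
    else:
        positions = rng.uniform(0, 500.0, size=(n, 2))
        # pull cluster members into spatial blobs, like real ensembles
        for members in memberships:
            center = rng.uniform(100.0, 400.0, size=2)
            idx = np.asarray(sorted(members), dtype=int)
            positions[idx] = center + rng.normal(0.0, 40.0, size=(len(idx), 2))
    return dff, spikes, memberships, positions


# --------------------------------------------------------------------------
# behavior
# --------------------------------------------------------------------------

@dataclass
class BehaviorSpec:
    """Planted running and whisking bouts.

    ``run_bouts`` are ``(start_s, end_s, speed_m_per_s)``; ``whisk_bouts``
    are ``(start_s, end_s, intensity)`` where intensity scales the extra
    temporal variance of the whisker-ROI pixels during the bout.
    """

    duration_s: float
    sample_rate_hz: float
    run_bouts: list = field(default_factory=list)
    whisk_bouts: list = field(default_factory=list)
    roi_shape: tuple[int, int] = (16, 16)
    seed: int = 0

    def __post_init__(self) -> None:
        for start, end, speed in self.run_bouts:
            if not (0 <= start < end <= self.duration_s):
                raise ValueError("run bout outside [0, duration]")
            if speed < 0:
                raise ValueError("speeds must be nonnegative")
        for start, end, _ in self.whisk_bouts:
            if not (0 <= start < end <= self.duration_s):
                raise ValueError("whisk bout outside [0, duration]")
        # overlapping run bouts with different speeds are contradictory
        bouts = sorted(self.run_bouts)
        for (s1, e1, v1), (s2, e2, v2) in zip(bouts, bouts[1:]):
            if s2 < e1 and v1 != v2:
                raise ValueError("overlapping run bouts with conflicting speeds")


def generate_behavior(spec: BehaviorSpec) -> BehaviorTrace:
    """Render the wheel-velocity series and whisker-ROI stack for a recording.

    Velocity equals the bout speed inside run bouts and 0 elsewhere.  The
    whisker stack is Gaussian pixel noise whose temporal SD is elevated by
    ``1 + 4 * intensity`` inside whisk bouts, emulating motion energy.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.sample_rate_hz))
    t = np.arange(n) / spec.sample_rate_hz
    velocity = np.zeros(n)
    for start, end, speed in spec.run_bouts:
        velocity[(t >= start) & (t < end)] = speed

    h, w = spec.roi_shape
    sd = np.ones(n)
    for start, end, intensity in spec.whisk_bouts:
        sd[(t >= start) & (t < end)] = 1.0 + 4.0 * float(intensity)
    stack = rng.normal(0.0, 1.0, size=(n, h, w)) * sd[:, None, None]
    return BehaviorTrace(velocity=velocity, whisker_stack=stack,
                         sample_rate=spec.sample_rate_hz)
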