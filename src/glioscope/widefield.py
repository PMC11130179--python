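"""Mesoscale dF/F analysis: quiet-wakefulness gating and per-pixel event metrics.

Movies are spatially downsampled (block mean), frames contaminated by running
(wheel speed above 0.043 m/s) or whisking are excluded, and on the earliest
300 s of quiet wakefulness each pixel's dF/F trace is scanned for calcium
events by thresholding at median + 3 SD, where the SD is a robust (MAD-based)
estimate of the baseline noise.  Four metrics summarize each pixel: activity
per minute (integrated dF/F), events per second, mean event amplitude, and
mean event duration.

Event detection details (see docs/methods.md): the trace is lightly smoothed
(0.5 s boxcar) before thresholding so single-frame noise excursions do not
register; event boundaries are then refined on the raw trace; and a single
supra-threshold run containing several transients (Poisson arrivals overlap)
is split wherever the smoothed trace takes another onset-sized upward step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import defaults
from .core import ActivityMovie, BehaviorTrace

__all__ = [
    "QuietEpochs",
    "PixelEventMetrics",
    "InsufficientQuietError",
    "downsample_movie",
    "detect_quiet_epochs",
    "detect_pixel_events",
    "compute_pixel_metrics",
]


class InsufficientQuietError(ValueError):
    """Raised when a recording has less quiet wakefulness than required."""


@dataclass
class QuietEpochs:
    """Frame-level quiet-wakefulness gating result."""

    quiet: np.ndarray              # bool per frame: neither running nor whisking
    selected: np.ndarray           # bool per frame: earliest `required_s` of quiet
    frame_rate: float
    required_s: float
    whisk_index: np.ndarray | None = None
    whisk_threshold: float = float("inf")

    @property
    def total_quiet_s(self) -> float:
        return float(self.quiet.sum()) / self.frame_rate

    @property
    def sufficient(self) -> bool:
        return self.total_quiet_s >= self.required_s


@dataclass
class PixelEventMetrics:
    """Per-pixel metric grids plus the detected event table."""

    activity_per_min: np.ndarray   # integrated dF/F per minute
    events_per_sec: np.ndarray
    mean_amplitude: np.ndarray     # dF/F
    mean_duration: np.ndarray      # s
    events: pd.DataFrame           # y, x, onset, offset, peak, amplitude, duration_s
    analysis_duration_s: float

    def metric(self, name: str) -> np.ndarray:
        return getattr(self, name)


METRIC_NAMES = ("activity_per_min", "events_per_sec", "mean_amplitude",
                "mean_duration")


def downsample_movie(movie: ActivityMovie, factor: int = defaults.DOWNSAMPLE_FACTOR
                     ) -> ActivityMovie:
    """Block-mean spatial pooling by ``factor``; edges that do not divide are trimmed.

    The pixel size scales by ``factor`` and the validity mask is pooled by
    majority vote.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return movie
    t, ny, nx = movie.dff.shape
    ny2, nx2 = ny // factor, nx // factor
    if ny2 == 0 or nx2 == 0:
        raise ValueError("factor larger than the field of view")
    trimmed = movie.dff[:, : ny2 * factor, : nx2 * factor]
    pooled = trimmed.reshape(t, ny2, factor, nx2, factor).mean(axis=(2, 4))
    vm = movie.valid_mask[: ny2 * factor, : nx2 * factor]
    vm_pooled = vm.reshape(ny2, factor, nx2, factor).mean(axis=(1, 3)) >= 0.5
    return ActivityMovie(dff=pooled, frame_rate=movie.frame_rate,
                         pixel_size=movie.pixel_size * factor,
                         valid_mask=vm_pooled)


def _whisk_motion_index(stack: np.ndarray) -> np.ndarray:
    """Per-frame mean absolute frame difference over the whisker ROI."""
    diff = np.abs(np.diff(stack, axis=0)).mean(axis=(1, 2))
    return np.concatenate([[diff[0]], diff])


def detect_quiet_epochs(behavior: BehaviorTrace,
                        run_threshold: float = defaults.RUN_SPEED_THRESHOLD_M_S,
                        required_s: float = defaults.QUIET_REQUIRED_S) -> QuietEpochs:
    """Flag quiet-wakefulness frames and select the earliest ``required_s`` of them.

    A frame is excluded if wheel speed exceeds ``run_threshold`` (m/s) or the
    whisker motion index exceeds a per-recording threshold (Otsu's threshold
    on the index histogram, applied only when the index is clearly bimodal;
    a recording without whisking excludes no frames on that account).

    The result's ``sufficient`` property is False when less than
    ``required_s`` of quiet is available; downstream metric computation then
    raises :class:`InsufficientQuietError`.
    """
    from skimage.filters import threshold_otsu

    speed = np.abs(behavior.velocity)
    running = speed > run_threshold

    index = _whisk_motion_index(behavior.whisker_stack)
    robust_sd = 1.4826 * np.median(np.abs(index - np.median(index)))
    whisk_threshold = float("inf")
    if np.ptp(index) > 0:
        thr = float(threshold_otsu(index))
        high = index[index > thr]
        # require a genuinely separated high-motion mode before excluding
        if high.size and np.median(high) > np.median(index) + 4.0 * robust_sd:
            whisk_threshold = thr
    whisking = index > whisk_threshold

    quiet = ~(running | whisking)
    n_req = int(round(required_s * behavior.sample_rate))
    selected = np.zeros_like(quiet)
    quiet_idx = np.flatnonzero(quiet)
    selected[quiet_idx[:n_req]] = True
    return QuietEpochs(quiet=quiet, selected=selected,
                       frame_rate=behavior.sample_rate, required_s=required_s,
                       whisk_index=index, whisk_threshold=whisk_threshold)


# --------------------------------------------------------------------------
# event detection
# --------------------------------------------------------------------------

def _block_median_baseline(traces: np.ndarray, frame_rate: float,
                           window_s: float = 10.0) -> np.ndarray:
    """Running-median baseline (T x P), computed on ~2 s blocks for speed."""
    t = traces.shape[0]
    block = max(1, int(round(frame_rate * window_s / 5.0)))
    n_blocks = max(1, t // block)
    trimmed = traces[: n_blocks * block]
    block_med = np.median(trimmed.reshape(n_blocks, block, -1), axis=1)
    if n_blocks >= 3:
        block_med = ndimage.median_filter(block_med, size=(min(5, n_blocks), 1),
                                          mode="nearest")
    baseline = np.repeat(block_med, block, axis=0)
    if baseline.shape[0] < t:
        pad = np.repeat(baseline[-1:], t - baseline.shape[0], axis=0)
        baseline = np.concatenate([baseline, pad], axis=0)
    return baseline


def _noise_sigma(traces: np.ndarray, frame_rate: float) -> np.ndarray:
    """Robust per-trace noise SD: 1.4826 * MAD after removing a 10 s median baseline."""
    resid = traces - _block_median_baseline(traces, frame_rate)
    med = np.median(resid, axis=0)
    return 1.4826 * np.median(np.abs(resid - med), axis=0)


def _smooth(traces: np.ndarray, frame_rate: float, smooth_s: float) -> np.ndarray:
    w = max(1, int(round(smooth_s * frame_rate)))
    if w <= 1:
        return traces
    return ndimage.uniform_filter1d(traces.astype(float), size=w, axis=0,
                                    mode="nearest")


def _runs_above(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive (start, stop) index pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], above.astype(np.int8), [0]])))
    return list(zip(idx[::2], idx[1::2] - 1))


def _onset_signal(raw: np.ndarray, w_on: int) -> np.ndarray:
    """Difference between the w_on-frame mean after t and before t.

    An instantaneous rise of height A at frame t0 produces a triangular bump
    peaking at exactly A at t0, however briefly the elevation is sustained,
    so overlapping transients remain individually visible.
    """
    n = len(raw)
    c = np.concatenate([[0.0], np.cumsum(raw)])
    window_mean = (c[w_on:] - c[:-w_on]) / w_on   # mean of raw[t .. t+w_on-1]
    out = np.zeros(n, dtype=float)
    out[w_on:n - w_on + 1] = window_mean[w_on:] - window_mean[:n - 2 * w_on + 1]
    return out


def _split_and_measure(raw: np.ndarray, smoothed: np.ndarray, runs, thr: float,
                       sigma: float, w: int, k: float, baseline: float,
                       frame_rate: float):
    """Refine run boundaries on the raw trace, split multi-transient runs, measure."""
    from scipy.signal import find_peaks

    n = len(raw)
    events = []  # (onset, offset, peak, amplitude)
    w_on = max(1, int(round(0.2 * frame_rate)))
    if sigma > 0:
        onset_sig = _onset_signal(raw, w_on)
        sigma_on = sigma * np.sqrt(2.0 / w_on)
    half = w // 2
    for a, b in runs:
        lo, hi = max(0, a - w), min(n - 1, b + w)
        seg_above = raw[lo:hi + 1] > thr
        if seg_above.any():
            onset = lo + int(np.argmax(seg_above))
            offset = lo + len(seg_above) - 1 - int(np.argmax(seg_above[::-1]))
        else:
            onset, offset = a, b
        splits: list[int] = []
        if sigma > 0 and offset - onset + 1 > 2 * w_on:
            # every transient onset, even inside an ongoing event, leaves an
            # onset-sized bump in the short-difference signal; peaks beyond
            # the run's own rising edge mark additional transients
            peaks, _ = find_peaks(onset_sig[onset:offset + 1],
                                  height=k * sigma_on,
                                  prominence=2.0 * sigma_on,
                                  distance=max(2, w_on))
            splits = sorted(onset + int(p) for p in peaks if p > 2 * w_on)
        bounds = [onset] + splits + [offset + 1]
        for j, (t0, t1) in enumerate(zip(bounds[:-1], bounds[1:])):
            t1 -= 1
            if t1 < t0:
                continue
            # keep the next transient's smoothed rise out of this event's
            # peak window (the boxcar smoother looks half a window ahead)
            p1 = t1 - half if j < len(bounds) - 2 and t1 - half >= t0 else t1
            peak = float(smoothed[t0:p1 + 1].max())
            pre = baseline if j == 0 else float(smoothed[max(t0 - half - 1, 0)])
            events.append((t0, t1, peak, peak - pre))
    return events


def detect_pixel_events(trace: np.ndarray, frame_rate: float,
                        k: float = defaults.EVENT_K_SD,
                        smooth_s: float = 0.5,
                        min_frames: int = 2,
                        merge_gap_frames: int = 2,
                        sigma: float | None = None) -> pd.DataFrame:
    """Detect calcium events in a single dF/F trace.

    Events are runs of the smoothed trace above median + ``k`` * SD (SD from
    a MAD estimate of baseline noise), with boundaries refined on the raw
    trace, runs shorter than ``min_frames`` discarded, runs separated by
    fewer than ``merge_gap_frames`` merged, and multi-transient runs split at
    additional onset-sized steps.  Returns a DataFrame with columns
    (onset, offset, peak, amplitude, duration_s).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ValueError("trace must be 1-D")
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace must be finite")
    if sigma is None:
        sigma = float(_noise_sigma(trace[:, None], frame_rate)[0])
    smoothed = _smooth(trace[:, None], frame_rate, smooth_s)[:, 0]
    med = float(np.median(trace))
    events = _detect_one(trace, smoothed, med, sigma, frame_rate, k,
                         smooth_s, min_frames, merge_gap_frames)
    return pd.DataFrame(events, columns=["onset", "offset", "peak", "amplitude"]
                        ).assign(duration_s=lambda d: (d.offset - d.onset + 1)
                                 / frame_rate)


def _detect_one(raw, smoothed, med, sigma, frame_rate, k, smooth_s,
                min_frames, merge_gap_frames):
    thr = med + k * sigma
    runs = _runs_above(smoothed > thr)
    runs = [(a, b) for a, b in runs if b - a + 1 >= min_frames]
    merged = []
    for a, b in runs:
        if merged and a - merged[-1][1] - 1 < merge_gap_frames:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    w = max(1, int(round(smooth_s * frame_rate)))
    return _split_and_measure(raw, smoothed, merged, thr, sigma, w, k, med,
                              frame_rate)


def compute_pixel_metrics(movie: ActivityMovie, quiet: QuietEpochs | None = None,
                          k: float = defaults.EVENT_K_SD,
                          smooth_s: float = 0.5) -> PixelEventMetrics:
    """Compute the four per-pixel activity metrics on quiet frames.

    ``activity_per_min`` is the integrated dF/F per minute (mean of the trace
    times frames per minute); ``events_per_sec`` is the detected event count
    over the analysis duration; amplitude and duration are means over the
    detected events (NaN where a pixel has none).  Metrics are NaN outside
    the movie's validity mask.
    """
    if quiet is not None:
        if not quiet.sufficient:
            raise InsufficientQuietError(
                f"only {quiet.total_quiet_s:.1f} s of quiet wakefulness "
                f"available; {quiet.required_s:.0f} s required")
        if len(quiet.selected) != movie.n_frames:
            raise ValueError("quiet epochs not aligned to movie frames")
        dff = movie.dff[quiet.selected]
    else:
        dff = movie.dff
    fs = movie.frame_rate
    t, ny, nx = dff.shape
    duration_s = t / fs
    flat = dff.reshape(t, -1).astype(float)
    valid_flat = movie.valid_mask.ravel()

    sigmas = _noise_sigma(flat, fs)
    smoothed = _smooth(flat, fs, smooth_s)
    medians = np.median(flat, axis=0)

    shape = (ny, nx)
    activity = np.full(ny * nx, np.nan)
    rate = np.full(ny * nx, np.nan)
    amp = np.full(ny * nx, np.nan)
    dur = np.full(ny * nx, np.nan)
    rows = []
    for p in np.flatnonzero(valid_flat):
        events = _detect_one(flat[:, p], smoothed[:, p], medians[p], sigmas[p],
                             fs, k, smooth_s, 2, 2)
        activity[p] = flat[:, p].mean() * fs * 60.0
        rate[p] = len(events) / duration_s
        if events:
            amps = [e[3] for e in events]
            durs = [(e[1] - e[0] + 1) / fs for e in events]
            amp[p] = float(np.mean(amps))
            dur[p] = float(np.mean(durs))
            y, x = divmod(p, nx)
            rows += [(y, x, e[0], e[1], e[2], e[3], (e[1] - e[0] + 1) / fs)
                     for e in events]
    events_df = pd.DataFrame(rows, columns=["y", "x", "onset", "offset", "peak",
                                            "amplitude", "duration_s"])
    return PixelEventMetrics(
        activity_per_min=activity.reshape(shape),
        events_per_sec=rate.reshape(shape),
        mean_amplitude=amp.reshape(shape),
        mean_duration=dur.reshape(shape),
        events=events_df,
        analysis_duration_s=duration_s,
    )
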