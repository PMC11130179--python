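"""Tumor-distance analysis: bands, near/far ratios, circular-shuffle regression.

Every pixel outside the tumor is assigned its Euclidean distance (um) to the
nearest tumor-edge pixel and a 0.75-mm band index.  Activity metrics are
summarized as the ratio of the mean inside the nearest band (<0.75 mm) to the
mean beyond 3 mm, and the distance-activity relation is tested by ordinary
least squares whose significance comes from a circular-shift permutation
null: the distance vector is rotated by a random offset along the raster
order of extramarginal pixels, which preserves the metric's spatial
autocorrelation structure, and the p-value is the fraction of shuffles whose
adjusted R^2 exceeds the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import defaults
from .tumor import TumorMask

__all__ = [
    "DistanceMap",
    "NearFarRatio",
    "ShuffleRegressionResult",
    "distance_map",
    "near_far_ratio",
    "band_profile",
    "raster_vectors",
    "shuffle_regression",
    "group_ratios",
]


@dataclass
class DistanceMap:
    """Per-pixel distance to the nearest tumor-edge pixel, with band indices."""

    distance: np.ndarray             # um; 0 inside the tumor
    band_index: np.ndarray           # floor(distance / band_width); -1 inside tumor
    extramarginal_mask: np.ndarray   # bool; pixels outside the tumor mass
    band_width: float                # um
    pixel_size: float                # um


def distance_map(tumor_mask, pixel_size: float | None = None,
                 band_width: float = defaults.BAND_WIDTH_UM) -> DistanceMap:
    """Euclidean distance transform (um) from the tumor edge.

    Accepts a :class:`~glioscope.tumor.TumorMask` or a boolean grid plus
    ``pixel_size``.  Tumor-interior pixels get distance 0 and are excluded
    from the extramarginal mask.  An empty mask or a mask covering the whole
    field of view is an error (no edge / no extramarginal pixels).
    """
    if isinstance(tumor_mask, TumorMask):
        mask = tumor_mask.mask
        pixel_size = tumor_mask.pixel_size
    else:
        mask = np.asarray(tumor_mask, dtype=bool)
        if pixel_size is None:
            raise ValueError("pixel_size required with a plain boolean mask")
    if not mask.any():
        raise ValueError("empty tumor mask: no edge to measure from")
    if mask.all():
        raise ValueError("tumor covers the full FOV: no extramarginal pixels")
    eroded = ndimage.binary_erosion(mask)
    edge = mask & ~eroded
    dist = ndimage.distance_transform_edt(~edge) * pixel_size
    dist[mask] = 0.0
    band = np.floor_divide(dist, band_width).astype(int)
    band[mask] = -1
    return DistanceMap(distance=dist, band_index=band, extramarginal_mask=~mask,
                       band_width=band_width, pixel_size=pixel_size)


@dataclass
class NearFarRatio:
    """Mean metric within the nearest band divided by the mean beyond the far cutoff."""

    ratio: float
    n_near: int
    n_far: int
    defined: bool = True
    metric: str = ""
    recording_id: str = ""
    expansion_class: str = ""
    genotype: str = ""


def near_far_ratio(metric_grid: np.ndarray, dmap: DistanceMap,
                   near_max: float = defaults.BAND_WIDTH_UM,
                   far_min: float = defaults.FAR_MIN_UM,
                   **labels) -> NearFarRatio:
    """mean(metric | 0 < d < near_max) / mean(metric | d > far_min).

    NaN metric pixels are ignored.  An empty near or far set (or a zero far
    mean) yields a flagged-undefined result rather than a silent drop.
    """
    grid = np.asarray(metric_grid, dtype=float)
    if grid.shape != dmap.distance.shape:
        raise ValueError("metric grid and distance map must be aligned")
    ok = dmap.extramarginal_mask & np.isfinite(grid)
    near = ok & (dmap.distance > 0) & (dmap.distance < near_max)
    far = ok & (dmap.distance > far_min)
    n_near, n_far = int(near.sum()), int(far.sum())
    if n_near == 0 or n_far == 0:
        return NearFarRatio(ratio=float("nan"), n_near=n_near, n_far=n_far,
                            defined=False, **labels)
    far_mean = grid[far].mean()
    if far_mean == 0:
        return NearFarRatio(ratio=float("nan"), n_near=n_near, n_far=n_far,
                            defined=False, **labels)
    return NearFarRatio(ratio=float(grid[near].mean() / far_mean),
                        n_near=n_near, n_far=n_far, defined=True, **labels)


def band_profile(metric_grid: np.ndarray, dmap: DistanceMap) -> pd.DataFrame:
    """Per-band summary (mean/median/SD/SEM/count) of a metric grid."""
    grid = np.asarray(metric_grid, dtype=float)
    if grid.shape != dmap.distance.shape:
        raise ValueError("metric grid and distance map must be aligned")
    ok = dmap.extramarginal_mask & np.isfinite(grid)
    rows = []
    for b in np.unique(dmap.band_index[ok]):
        vals = grid[ok & (dmap.band_index == b)]
        rows.append({
            "band_index": int(b),
            "distance_lo_um": b * dmap.band_width,
            "distance_hi_um": (b + 1) * dmap.band_width,
            "n_pixels": int(vals.size),
            "mean": float(vals.mean()),
            "median": float(np.median(vals)),
            "sd": float(vals.std(ddof=0)),
            "sem": float(vals.std(ddof=0) / np.sqrt(vals.size)),
        })
    return pd.DataFrame(rows)


def raster_vectors(metric_grid: np.ndarray, dmap: DistanceMap):
    """Aligned (metric, distance) vectors over extramarginal pixels, raster order.

    Row-major order is the fixed pixel ordering used for circular shuffles.
    """
    grid = np.asarray(metric_grid, dtype=float)
    ok = dmap.extramarginal_mask & np.isfinite(grid) & (dmap.distance > 0)
    return grid[ok], dmap.distance[ok]


@dataclass
class ShuffleRegressionResult:
    """Observed distance-regression fit and its circular-shuffle p-value."""

    observed_r2: float
    observed_adjusted_r2: float
    slope: float
    intercept: float
    n_shuffles: int
    p_value: float                  # fraction of shuffles with strictly higher R^2
    p_value_corrected: float        # (count + 1) / (n_shuffles + 1)
    n: int
    seed: int


def _adjusted_r2(r2: float | np.ndarray, n: int):
    """Adjusted R^2 for a single-predictor OLS fit."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def _all_rotation_r2(metric: np.ndarray, distance: np.ndarray) -> np.ndarray:
    """R^2 of metric ~ roll(distance, j) for every offset j in [0, N-1], via FFT.

    Circular rotation leaves both variances unchanged, so only the
    cross-covariance varies with the offset; the full set of N circular
    cross-covariances is one FFT product.
    """
    mc = metric - metric.mean()
    dc = distance - distance.mean()
    denom = np.sum(mc ** 2) * np.sum(dc ** 2)
    if denom == 0:
        return np.zeros(len(metric))
    cross = np.fft.ifft(np.fft.fft(mc) * np.conj(np.fft.fft(dc))).real
    return cross ** 2 / denom


def shuffle_regression(metric_values: np.ndarray, distances: np.ndarray,
                       n_shuffles: int = defaults.N_SHUFFLES,
                       seed: int = 0) -> ShuffleRegressionResult:
    """OLS of metric on tumor distance with a circular-shuffle permutation null.

    The distance vector is circularly rotated by a uniform random offset in
    [1, N-1] for each shuffle; p = (# shuffles with adjusted R^2 strictly
    above the observed) / n_shuffles.  A zero-variance metric yields
    R^2 = 0 and p = 1 by convention.
    """
    m = np.asarray(metric_values, dtype=float)
    d = np.asarray(distances, dtype=float)
    if m.shape != d.shape or m.ndim != 1:
        raise ValueError("metric and distance vectors must be aligned 1-D")
    n = len(m)
    if n < 10:
        raise ValueError("need at least 10 pixels for the regression")
    if m.std() == 0 or d.std() == 0:
        return ShuffleRegressionResult(
            observed_r2=0.0, observed_adjusted_r2=0.0, slope=0.0,
            intercept=float(m.mean()), n_shuffles=n_shuffles, p_value=1.0,
            p_value_corrected=1.0, n=n, seed=seed)

    r2_all = _all_rotation_r2(m, d)
    observed_r2 = float(r2_all[0])
    slope = float(np.cov(m, d, ddof=0)[0, 1] / d.var())
    intercept = float(m.mean() - slope * d.mean())

    rng = np.random.default_rng(seed)
    offsets = rng.integers(1, n, size=n_shuffles)
    # adjusted R^2 is monotone in R^2 at fixed n, so compare R^2 directly
    count = int(np.count_nonzero(r2_all[offsets] > observed_r2))
    return ShuffleRegressionResult(
        observed_r2=observed_r2,
        observed_adjusted_r2=float(_adjusted_r2(observed_r2, n)),
        slope=slope, intercept=intercept, n_shuffles=n_shuffles,
        p_value=count / n_shuffles,
        p_value_corrected=(count + 1) / (n_shuffles + 1),
        n=n, seed=seed)


def group_ratios(ratios: list[NearFarRatio]) -> pd.DataFrame:
    """Tidy table of near/far ratios keyed by (genotype, expansion_class, metric).

    Undefined ratios are kept as rows with ``defined = False`` so they are
    visible rather than silently dropped; empty groups simply do not appear
    (a warning notes any undefined entries).
    """
    n_undef = sum(not r.defined for r in ratios)
    if n_undef:
        warnings.warn(f"{n_undef} undefined near/far ratio(s) flagged in table")
    return pd.DataFrame([{
        "genotype": r.genotype,
        "expansion_class": r.expansion_class,
        "metric": r.metric,
        "recording_id": r.recording_id,
        "ratio": r.ratio,
        "n_near": r.n_near,
        "n_far": r.n_far,
        "defined": r.defined,
    } for r in ratios])
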