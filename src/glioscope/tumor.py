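"""Tumor infiltration (CV/day) and local expansion (um^2/day) across sessions.

Two complementary statistics quantify what serial tumor snapshots show:

* **CV/day** — the coefficient of variation (population SD / mean) of the
  pixel-wise ratio between two sessions' images, divided by the number of
  days between them.  It is scale-free, so global brightness drift between
  sessions does not register, while any spatial redistribution of tumor
  fluorescence (infiltration, motility, morphology change) does.
* **Expansion rate** — the change in segmented tumor area per day, classified
  as *slow* (<= 1e5 um^2/day) or *fast* (> 1e5 um^2/day).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from . import defaults
from .core import SessionImage

__all__ = [
    "TumorMask",
    "IntervalRecord",
    "segment_tumor",
    "cv_per_day",
    "cv_per_day_pixelwise",
    "expansion_rate",
    "classify_expansion",
    "summarize_percentile_timecourse",
    "change_rate_image",
    "normalize_animal_images",
    "analyze_series",
]


@dataclass
class TumorMask:
    """Boolean tumor-mass mask with its area and edge pixels."""

    mask: np.ndarray
    pixel_size: float
    empty: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area(self) -> float:
        """Tumor area in um^2 (pixel count x pixel_size^2)."""
        return float(self.mask.sum()) * self.pixel_size ** 2

    @property
    def edge_pixels(self) -> np.ndarray:
        """(n, 2) coordinates of mask pixels on the mask boundary."""
        if not self.mask.any():
            return np.empty((0, 2), dtype=int)
        eroded = ndimage.binary_erosion(self.mask)
        return np.argwhere(self.mask & ~eroded)


@dataclass
class IntervalRecord:
    """Per-interval statistics between two consecutive sessions."""

    day_start: int
    day_end: int
    cv_per_day: float
    expansion_rate: float          # um^2/day, may be negative
    expansion_class: str           # "slow" | "fast"
    ratio_image: np.ndarray | None = None
    animal_id: str = ""
    genotype: str = ""

    @property
    def days(self) -> int:
        return self.day_end - self.day_start

    @property
    def midpoint_day(self) -> float:
        return 0.5 * (self.day_start + self.day_end)


def segment_tumor(img: SessionImage) -> TumorMask:
    """Segment the tumor mass from a tumor-channel snapshot.

    Otsu's threshold on log-intensity provides a first split; the final mask
    is the half-maximum contour between the foreground and background median
    levels, keeping the largest connected component (hole-filled).  An image
    with no foreground yields an explicit empty-mask result rather than an
    exception.
    """
    px = img.pixels
    finite = px[np.isfinite(px)]
    if finite.size == 0 or np.ptp(finite) == 0:
        return TumorMask(mask=np.zeros_like(px, dtype=bool),
                         pixel_size=img.pixel_size, empty=True)
    logp = np.log1p(np.clip(px, 0, None))
    try:
        thr = threshold_otsu(logp)
    except ValueError:
        return TumorMask(mask=np.zeros_like(px, dtype=bool),
                         pixel_size=img.pixel_size, empty=True)
    rough = logp > thr
    if not rough.any() or rough.all():
        return TumorMask(mask=np.zeros_like(px, dtype=bool),
                         pixel_size=img.pixel_size, empty=True)
    # half-maximum refinement between foreground and background levels
    fg = np.median(px[rough])
    bg = np.median(px[~rough])
    half = bg + 0.5 * (fg - bg)
    mask = px >= half
    labels, n = ndimage.label(mask)
    if n == 0:
        return TumorMask(mask=mask, pixel_size=img.pixel_size, empty=True)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    return TumorMask(mask=mask, pixel_size=img.pixel_size, empty=False)


def _ratio_and_valid(img1: SessionImage, img2: SessionImage,
                     valid_mask: np.ndarray | None):
    if img1.pixels.shape != img2.pixels.shape:
        raise ValueError("images must share a shape")
    if img1.pixel_size != img2.pixel_size:
        raise ValueError("images must share a pixel size")
    days = img2.day - img1.day
    if days <= 0:
        raise ValueError("img2 must be acquired after img1")
    valid = (np.ones_like(img1.pixels, dtype=bool) if valid_mask is None
             else np.asarray(valid_mask, dtype=bool))
    # exclude near-zero denominators (vasculature / masked-out pixels)
    floor = 0.01 * img1.pixels[valid].mean() if valid.any() else 0.0
    valid = valid & (img1.pixels > floor)
    if not valid.any():
        raise ValueError("no valid pixels for ratio image")
    ratio = np.full_like(img1.pixels, np.nan, dtype=float)
    ratio[valid] = img2.pixels[valid] / img1.pixels[valid]
    return ratio, valid, days


def cv_per_day(img1: SessionImage, img2: SessionImage,
               valid_mask: np.ndarray | None = None):
    """CV/day between two serial snapshots of the same field of view.

    The later image is divided by the earlier one pixel-wise over the valid
    mask; CV/day = population SD(ratio) / (mean(ratio) * days).  Returns the
    scalar and the ratio image (NaN outside the valid mask) for rendering.
    """
    ratio, valid, days = _ratio_and_valid(img1, img2, valid_mask)
    vals = ratio[valid]
    mean = vals.mean()
    if mean == 0:
        raise ValueError("ratio image has zero mean")
    cv = float(vals.std(ddof=0) / (mean * days))
    return cv, ratio


def cv_per_day_pixelwise(images: list[SessionImage],
                         valid_mask: np.ndarray | None = None) -> float:
    """Temporal variant: CV/day computed per pixel across sessions, then averaged.

    For each valid pixel, the CV of its intensity across all sessions is
    divided by the mean day spacing; the per-pixel values are averaged.
    Exposed as a clearly named alternative to the primary ratio-image
    statistic computed by :func:`cv_per_day`.
    """
    if len(images) < 2:
        raise ValueError("need at least two sessions")
    stack = np.stack([im.pixels for im in images])
    days = np.array([im.day for im in images], dtype=float)
    if np.any(np.diff(days) <= 0):
        raise ValueError("sessions must be in increasing day order")
    valid = (np.ones(stack.shape[1:], dtype=bool) if valid_mask is None
             else np.asarray(valid_mask, dtype=bool))
    if not valid.any():
        raise ValueError("no valid pixels")
    mean = stack.mean(axis=0)
    valid = valid & (mean > 0.01 * mean[valid].mean())
    sd = stack.std(axis=0, ddof=0)
    cv = sd[valid] / mean[valid]
    mean_spacing = float(np.mean(np.diff(days)))
    return float(cv.mean() / mean_spacing)


def expansion_rate(mask1: TumorMask, mask2: TumorMask, days: float) -> float:
    """Local expansion rate (area2 - area1) / days in um^2/day; may be negative."""
    if days <= 0:
        raise ValueError("days must be positive")
    return (mask2.area - mask1.area) / days


def classify_expansion(rate: float,
                       threshold: float = defaults.FAST_EXPANSION_UM2_PER_DAY) -> str:
    """Classify a signed expansion rate: "fast" iff strictly above threshold."""
    if not np.isfinite(rate):
        raise ValueError("rate must be finite")
    return "fast" if rate > threshold else "slow"


def change_rate_image(img1: SessionImage, img2: SessionImage, days: float | None = None,
                      valid_mask: np.ndarray | None = None,
                      clip: tuple[float, float] = (0.5, 1.5)):
    """Daily change-rate image for visualization.

    The raw grid is ratio / days; the rendered grid is additionally
    normalized by its own mean and clipped to ``clip`` (identical sessions
    render as a uniform 1.0).  Returns ``(rendered, raw)``.
    """
    ratio, valid, d = _ratio_and_valid(img1, img2, valid_mask)
    if days is not None and days != d:
        raise ValueError("days argument disagrees with image metadata")
    raw = ratio / d
    rendered = raw / np.nanmean(raw[valid])
    rendered = np.clip(rendered, clip[0], clip[1])
    rendered[~valid] = np.nan
    return rendered, raw


def normalize_animal_images(images: list[SessionImage]) -> list[SessionImage]:
    """Scale all of one animal's snapshots by their common grand-mean intensity.

    Removes lamp/exposure drift without altering CV/day (which is scale-free).
    """
    grand = float(np.mean([im.pixels.mean() for im in images]))
    if grand <= 0:
        raise ValueError("images must have positive mean intensity")
    return [SessionImage(pixels=im.pixels / grand, pixel_size=im.pixel_size,
                         day=im.day, channel=im.channel, animal_id=im.animal_id,
                         genotype=im.genotype) for im in images]


def analyze_series(images: list[SessionImage],
                   valid_mask: np.ndarray | None = None,
                   fast_threshold: float = defaults.FAST_EXPANSION_UM2_PER_DAY,
                   normalize: bool = True) -> list[IntervalRecord]:
    """Full per-animal interval analysis of a serial tumor snapshot series.

    Segments every session, then for each consecutive pair computes CV/day,
    the expansion rate and its slow/fast class.
    """
    if len(images) < 2:
        raise ValueError("need at least two sessions")
    if normalize:
        images = normalize_animal_images(images)
    masks = [segment_tumor(im) for im in images]
    records = []
    for (im1, m1), (im2, m2) in zip(zip(images, masks), zip(images[1:], masks[1:])):
        cv, ratio = cv_per_day(im1, im2, valid_mask)
        rate = expansion_rate(m1, m2, im2.day - im1.day)
        records.append(IntervalRecord(
            day_start=im1.day, day_end=im2.day, cv_per_day=cv,
            expansion_rate=rate,
            expansion_class=classify_expansion(rate, fast_threshold),
            ratio_image=ratio, animal_id=im1.animal_id, genotype=im1.genotype))
    return records


def summarize_percentile_timecourse(
    records: list[IntervalRecord],
    bin_width: int = defaults.PERCENTILE_BIN_DAYS,
    day_range: tuple[int, int] = defaults.PERCENTILE_DAY_RANGE,
    q: float = defaults.PERCENTILE_Q,
    value: str = "cv_per_day",
) -> pd.DataFrame:
    """Per-animal, per-10-day-bin percentile summary of interval statistics.

    Each interval is assigned to the bin containing its midpoint day; bins run
    ``[lo, lo + bin_width)`` across ``day_range``.  Within each (animal, bin)
    the ``q``-th percentile (linear interpolation) of the chosen statistic is
    reported; empty bins are omitted.
    """
    lo, hi = day_range
    rows = []
    by_animal: dict[str, dict[int, list[float]]] = {}
    for rec in records:
        mid = rec.midpoint_day
        if not (lo <= mid < hi + bin_width):
            continue
        b = int((mid - lo) // bin_width)
        by_animal.setdefault(rec.animal_id, {}).setdefault(b, []).append(
            getattr(rec, value))
    for animal, bins in sorted(by_animal.items()):
        for b, vals in sorted(bins.items()):
            rows.append({
                "animal_id": animal,
                "bin_start_day": lo + b * bin_width,
                "bin_end_day": lo + (b + 1) * bin_width,
                "n_intervals": len(vals),
                f"p{q:g}_{value}": float(np.percentile(vals, q)),
            })
    return pd.DataFrame(rows)
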