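"""Shared in-memory containers for imaging sessions and movies.

These are deliberately thin: plain dataclasses wrapping numpy arrays plus the
acquisition metadata every stage needs (pixel size, frame rate, postnatal day).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CHANNELS = ("tumor", "calcium", "glutamate")
GENOTYPES = ("3xCR", "GPC6", "control")


@dataclass
class SessionImage:
    """One registered fluorescence snapshot from a chronic imaging session.

    Parameters
    ----------
    pixels : 2-D float array, nonnegative intensities.
    pixel_size : um per pixel (square pixels).
    day : postnatal day of acquisition.
    channel : one of {"tumor", "calcium", "glutamate"}.
    """

    pixels: np.ndarray
    pixel_size: float
    day: int
    channel: str = "tumor"
    animal_id: str = ""
    genotype: str = "control"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("SessionImage.pixels must be 2-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("SessionImage.pixels must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.day < 0:
            raise ValueError("day must be nonnegative")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")


@dataclass
class ActivityMovie:
    """A T x Y x X dF/F stack with frame rate, pixel size and validity mask."""

    dff: np.ndarray
    frame_rate: float
    pixel_size: float
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=np.float32)
        if self.dff.ndim != 3:
            raise ValueError("ActivityMovie.dff must be T x Y x X")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.dff.shape[1:], dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.dff.shape[1:]:
                raise ValueError("valid_mask shape must match frame shape")

    @property
    def n_frames(self) -> int:
        return self.dff.shape[0]

    @property
    def duration_s(self) -> float:
        return self.dff.shape[0] / self.frame_rate


@dataclass
class BehaviorTrace:
    """Wheel velocity plus a whisker-ROI image stack, frame-aligned to a movie."""

    velocity: np.ndarray          # m/s, one sample per movie frame
    whisker_stack: np.ndarray     # T x h x w pixel intensities
    sample_rate: float            # Hz

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.whisker_stack = np.asarray(self.whisker_stack, dtype=float)
        if self.velocity.ndim != 1:
            raise ValueError("velocity must be 1-D")
        if self.whisker_stack.ndim != 3:
            raise ValueError("whisker_stack must be T x h x w")
        if len(self.velocity) != self.whisker_stack.shape[0]:
            raise ValueError("velocity and whisker_stack must be frame-aligned")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


@dataclass
class NeuronTraceSet:
    """Cellular-resolution traces: raw dF/F and deconvolved activity per neuron."""

    dff: np.ndarray                   # N x T
    frame_rate: float
    positions: np.ndarray | None = None   # N x 2, (y, x) in um
    ddff: np.ndarray | None = None        # N x T, nonnegative deconvolved
    location_tag: str = "extramarginal"   # intramarginal | extramarginal | control
    time_bin: str = ""                    # early | mid | late
    animal_id: str = ""
    genotype: str = "control"

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        if self.dff.ndim != 2:
            raise ValueError("dff must be N x T")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.ddff is not None:
            self.ddff = np.asarray(self.ddff, dtype=float)
            if self.ddff.shape != self.dff.shape:
                raise ValueError("ddff shape must match dff")
            if np.any(self.ddff < 0):
                raise ValueError("ddff must be nonnegative")

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]
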