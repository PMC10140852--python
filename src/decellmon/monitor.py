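"""Image-based process monitoring for perfusion decellularization.

The monitored signal ("process variable") is the arithmetic mean grayscale
intensity of a fixed rectangular region of interest (ROI) in each time-lapse
frame, expressed as a percentage of the 8-bit full scale (255).  As the organ
(or dye-filled phantom) clears, the backlit ROI brightens and the process
variable rises along a sigmoid toward a plateau.  The run is declared
complete by a windowed stopping rule: once the last ``window_n`` smoothed
values vary by no more than ``k_percent`` percent of their window mean, the
plateau has been reached.

Conventions
-----------
* Pixel intensities are 8-bit: black = 0, white = 255.
* ROI rectangles are 0-based and half-open: ``x0 <= x < x1``,
  ``y0 <= y < y1``.
* All times are minutes.
* RGB frames are reduced to their *green* channel before averaging, because
  the rig backlights the chamber with a ~530 nm (green) LED panel, so the
  green channel carries essentially all of the photometric signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "Frame",
    "FrameSeries",
    "ROI",
    "ProcessTrace",
    "StoppingRule",
    "StopDecision",
    "FormatError",
    "to_grayscale",
    "mean_intensity",
    "to_percent",
    "smooth_trace",
    "should_stop",
    "run_monitor",
    "replay_stop_rule",
    "normalize_time_to_flow",
]

#: Kernel truncation, in standard deviations, used everywhere smoothing occurs.
GAUSSIAN_TRUNCATE = 4.0


class FormatError(ValueError):
    """Raised for images whose layout the monitor cannot interpret."""


@dataclass
class Frame:
    """A single 8-bit time-lapse frame.

    Parameters
    ----------
    pixels
        ``(height, width)`` grayscale or ``(height, width, 3)`` RGB array of
        dtype ``uint8``.
    timestamp_min
        Acquisition time in minutes from the start of the run (nonnegative).
    """

    pixels: np.ndarray
    timestamp_min: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            raise FormatError(
                f"frame pixels must be uint8, got {self.pixels.dtype}"
            )
        if self.pixels.ndim not in (2, 3):
            raise FormatError(
                f"frame must be 2-D grayscale or 3-D RGB, got shape {self.pixels.shape}"
            )
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise FormatError(
                f"multi-channel frames must have 3 channels, got {self.pixels.shape[2]}"
            )
        if self.timestamp_min < 0:
            raise ValueError(f"timestamp_min must be >= 0, got {self.timestamp_min}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]


@dataclass
class FrameSeries:
    """A time-ordered sequence of frames from one monitoring session."""

    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [f.timestamp_min for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def times_min(self) -> np.ndarray:
        return np.array([f.timestamp_min for f in self.frames], dtype=float)


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest, 0-based, half-open on both axes."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (0 <= self.x0 < self.x1 and 0 <= self.y0 < self.y1):
            raise ValueError(
                "ROI must satisfy 0 <= x0 < x1 and 0 <= y0 < y1 "
                f"(half-open bounds); got {self}"
            )

    @property
    def area(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def validate_for(self, frame: Frame) -> None:
        if self.x1 > frame.width or self.y1 > frame.height:
            raise ValueError(
                f"ROI {self} exceeds frame bounds {frame.width}x{frame.height}"
            )

    def crop(self, pixels: np.ndarray) -> np.ndarray:
        return pixels[self.y0 : self.y1, self.x0 : self.x1]


@dataclass
class ProcessTrace:
    """Raw and smoothed process-variable series, in percent of full scale."""

    times_min: np.ndarray
    raw_percent: np.ndarray
    smoothed_percent: np.ndarray

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.raw_percent = np.asarray(self.raw_percent, dtype=float)
        self.smoothed_percent = np.asarray(self.smoothed_percent, dtype=float)
        n = len(self.times_min)
        if len(self.raw_percent) != n or len(self.smoothed_percent) != n:
            raise ValueError("times, raw and smoothed sequences must have equal length")
        if n > 1 and np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times_min must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_min)


@dataclass(frozen=True)
class StoppingRule:
    """Windowed plateau stopping rule.

    The run stops at the first frame for which the most recent ``window_n``
    smoothed process-variable values have a range (max minus min) no larger
    than ``k_percent`` percent of their mean.  Defaults follow the monitoring
    software's operating settings: a 10-sample window and a 3 % band, with a
    Gaussian smoother of 2 samples applied to the trace beforehand.
    """

    window_n: int = 10
    k_percent: float = 3.0
    smoothing_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.window_n < 2:
            raise ValueError(f"window_n must be >= 2, got {self.window_n}")
        if self.k_percent <= 0:
            raise ValueError(f"k_percent must be > 0, got {self.k_percent}")
        if self.smoothing_sigma <= 0:
            raise ValueError(
                f"smoothing_sigma must be > 0, got {self.smoothing_sigma}"
            )


@dataclass(frozen=True)
class StopDecision:
    """Outcome of one stopping-rule evaluation, with diagnostics."""

    stop: bool
    window_range: Optional[float] = None
    window_mean: Optional[float] = None
    threshold: Optional[float] = None


def to_grayscale(frame: Frame) -> Frame:
    """Reduce a frame to a single channel.

    Single-channel frames pass through unchanged.  RGB frames are reduced to
    their green channel (the rig's green backlight concentrates the signal
    there); other channel counts raise :class:`FormatError`.
    """
    if frame.n_channels == 1:
        return frame
    return Frame(
        pixels=np.ascontiguousarray(frame.pixels[:, :, 1]),
        timestamp_min=frame.timestamp_min,
    )


def mean_intensity(frame: Frame, roi: ROI) -> float:
    """Exact arithmetic mean of the grayscale pixels inside ``roi``.

    The mean is computed in floating point over the integer pixel values
    (no intermediate truncation), so e.g. a 2x2 block of {0, 255, 255, 0}
    averages to exactly 127.5.
    """
    if frame.n_channels != 1:
        raise FormatError("mean_intensity requires a single-channel frame")
    roi.validate_for(frame)
    block = roi.crop(frame.pixels)
    if block.size == 0:
        raise ValueError(f"ROI {roi} selects no pixels")
    return float(block.astype(np.float64).mean())


def to_percent(value: float) -> float:
    """Map an 8-bit intensity (0–255) onto the 0–100 % display scale."""
    if not 0 <= value <= 255:
        raise ValueError(f"intensity must lie in [0, 255], got {value}")
    return value / 255.0 * 100.0


def smooth_trace(raw: Sequence[float], sigma: float) -> np.ndarray:
    """Gaussian-smooth a 1-D trace.

    Discrete Gaussian kernel of standard deviation ``sigma`` samples,
    truncated at 4σ, weights normalized to unit sum, with reflect padding at
    both ends; output has the same length as the input.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("cannot smooth an empty trace")
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return gaussian_filter1d(raw, sigma, mode="reflect", truncate=GAUSSIAN_TRUNCATE)


def should_stop(trace: ProcessTrace, rule: StoppingRule) -> StopDecision:
    """Evaluate the plateau stopping rule on the current trace.

    Returns a negative decision while fewer than ``rule.window_n`` samples
    exist.  Otherwise the rule fires iff the range of the last ``window_n``
    *smoothed* values is at most ``k_percent/100`` times their mean.
    Diagnostics carry the window range, window mean, and the threshold the
    range was compared against.
    """
    n = len(trace)
    if n == 0:
        raise ValueError("trace is empty")
    if n < rule.window_n:
        return StopDecision(stop=False)
    window = trace.smoothed_percent[-rule.window_n :]
    wrange = float(window.max() - window.min())
    wmean = float(window.mean())
    threshold = rule.k_percent / 100.0 * wmean
    return StopDecision(
        stop=wrange <= threshold,
        window_range=wrange,
        window_mean=wmean,
        threshold=threshold,
    )


def run_monitor(
    frames: Iterable[Frame],
    roi: ROI,
    rule: StoppingRule,
) -> tuple[ProcessTrace, Optional[float]]:
    """Run the full monitoring loop over a time-ordered frame source.

    Per frame: grayscale reduction, ROI mean, percent scaling, append to the
    raw trace, re-smooth the *entire* trace, and evaluate the stopping rule.
    Frame consumption ends at the first frame that triggers the rule; its
    timestamp is returned as the stop time.  An exhausted source without a
    trigger returns ``stop_time = None`` (not an error).
    """
    times: list[float] = []
    raw: list[float] = []
    trace = None
    stop_time: Optional[float] = None
    for frame in frames:
        if times and frame.timestamp_min <= times[-1]:
            raise ValueError("frames must be strictly time-ordered")
        gray = to_grayscale(frame)
        raw.append(to_percent(mean_intensity(gray, roi)))
        times.append(frame.timestamp_min)
        smoothed = smooth_trace(raw, rule.smoothing_sigma)
        trace = ProcessTrace(
            times_min=np.array(times),
            raw_percent=np.array(raw),
            smoothed_percent=smoothed,
        )
        if should_stop(trace, rule).stop:
            stop_time = frame.timestamp_min
            break
    if trace is None:
        raise ValueError("frame source yielded no frames")
    return trace, stop_time


def replay_stop_rule(
    times_min: Sequence[float],
    raw_percent: Sequence[float],
    rule: StoppingRule,
) -> Optional[float]:
    """Stop time the streaming monitor would report on a recorded raw trace.

    Vectorized but exact: for every prefix of the trace it reproduces the
    last-``window_n`` smoothed values that :func:`run_monitor` would see
    after re-smoothing that prefix, exploiting the fact that with a kernel
    radius ``r`` and reflect padding, the last ``N`` smoothed values of a
    prefix depend only on its last ``N + 2r`` raw samples.
    """
    times = np.asarray(times_min, dtype=float)
    raw = np.asarray(raw_percent, dtype=float)
    if times.shape != raw.shape:
        raise ValueError("times and raw trace must have equal length")
    n = raw.size
    N = rule.window_n
    if n < N:
        return None
    sigma = rule.smoothing_sigma
    r = int(GAUSSIAN_TRUNCATE * sigma + 0.5)  # scipy's kernel radius
    L = N + 2 * r

    k_frac = rule.k_percent / 100.0

    # Short prefixes (fewer than L samples): smooth each prefix directly.
    for i in range(N, min(L, n + 1)):
        window = smooth_trace(raw[:i], sigma)[-N:]
        if window.max() - window.min() <= k_frac * window.mean():
            return float(times[i - 1])
    if n < L:
        return None

    # Long prefixes: each row j holds raw[j : j + L], standing for the prefix
    # ending at sample j + L - 1.  Reflect smoothing each row reproduces the
    # full-prefix smoothing exactly on the last N positions, because those
    # positions sit at least r samples away from the row's left edge.
    rows = sliding_window_view(raw, L)
    smoothed = gaussian_filter1d(
        rows.astype(float), sigma, axis=1, mode="reflect", truncate=GAUSSIAN_TRUNCATE
    )
    win = smoothed[:, -N:]
    ranges = win.max(axis=1) - win.min(axis=1)
    means = win.mean(axis=1)
    hits = np.nonzero(ranges <= k_frac * means)[0]
    if hits.size == 0:
        return None
    return float(times[hits[0] + L - 1])


def normalize_time_to_flow(stop_time_min: float, flow_rate_mL_per_h: float) -> float:
    """Total perfusate volume (mL) delivered by the pump at the stop time.

    This normalizes endpoint times across runs performed at different
    constant flow rates: ``volume = flow × time / 60``.
    """
    if stop_time_min <= 0:
        raise ValueError(f"stop_time_min must be > 0, got {stop_time_min}")
    if flow_rate_mL_per_h <= 0:
        raise ValueError(
            f"flow_rate_mL_per_h must be > 0, got {flow_rate_mL_per_h}"
        )
    return flow_rate_mL_per_h * stop_time_min / 60.0
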