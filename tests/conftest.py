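import numpy as np
import pytest

from decellmon.monitor import ROI, Frame, ProcessTrace
from decellmon.phantom import PhantomScene


@pytest.fixture
def tiny_scene() -> PhantomScene:
    """A small noise-free phantom scene for fast rendering tests."""
    return PhantomScene(
        width_px=32, height_px=24, center_x=16.0, center_y=12.0,
        semi_axis_x=10.0, semi_axis_y=8.0, backlight_intensity=250,
        background_intensity=30, pixel_noise_sd=0.0, seed=0,
    )


@pytest.fixture
def inscribed_roi() -> ROI:
    """Rectangle fully inside tiny_scene's heart ellipse."""
    return ROI(x0=10, y0=8, x1=22, y1=16)


def uniform_frame(value: int, t: float = 0.0, shape=(8, 8)) -> Frame:
    return Frame(pixels=np.full(shape, value, dtype=np.uint8), timestamp_min=t)


def trace_from_smoothed(values) -> ProcessTrace:
    """Trace whose smoothed channel is set directly (raw mirrors it)."""
    values = np.asarray(values, dtype=float)
    times = np.arange(len(values), dtype=float)
    return ProcessTrace(times_min=times, raw_percent=values, smoothed_percent=values)
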