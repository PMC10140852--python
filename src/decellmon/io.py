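"""File formats: data.txt traces, concentration CSVs, and PNG frame stacks.

All formats are plain text or standard PNG and round-trip exactly:
``read(write(x)) == x`` bit-for-bit on the numeric payload.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .endpoint import ConcentrationSeries
from .monitor import Frame, FrameSeries, ProcessTrace

__all__ = [
    "write_data_txt",
    "read_data_txt",
    "write_series_csv",
    "read_series_csv",
    "write_frames",
    "read_frames",
    "frame_filename",
]

DATA_TXT_HEADER = "time_min\traw_percent\tsmoothed_percent"
SERIES_CSV_COLUMNS = ["time_min", "value", "analyte", "units"]
_FRAME_RE = re.compile(r"^frame_(\d+)_([0-9.]+)\.png$")


def write_data_txt(
    path: str | Path, trace: ProcessTrace, stop_time_min: Optional[float] = None
) -> Path:
    """Write the monitoring trace in the data.txt format.

    Header line, then one tab-separated row per frame with full-precision
    (round-trippable) floats.  A detected stop event is appended as a final
    comment line ``# stop_time_min=<value>``.
    """
    path = Path(path)
    lines = [DATA_TXT_HEADER]
    for t, r, s in zip(trace.times_min, trace.raw_percent, trace.smoothed_percent):
        lines.append(f"{float(t)!r}\t{float(r)!r}\t{float(s)!r}")
    if stop_time_min is not None:
        lines.append(f"# stop_time_min={float(stop_time_min)!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_data_txt(path: str | Path) -> tuple[ProcessTrace, Optional[float]]:
    """Read a data.txt trace back, returning the trace and any stop time."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != DATA_TXT_HEADER:
        raise ValueError(f"{path}: missing or malformed data.txt header")
    stop_time: Optional[float] = None
    times, raw, smoothed = [], [], []
    for line in lines[1:]:
        if not line.strip():
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*stop_time_min=(\S+)", line)
            if m:
                stop_time = float(m.group(1))
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}: malformed row {line!r}")
        times.append(float(parts[0]))
        raw.append(float(parts[1]))
        smoothed.append(float(parts[2]))
    trace = ProcessTrace(
        times_min=np.array(times),
        raw_percent=np.array(raw),
        smoothed_percent=np.array(smoothed),
    )
    return trace, stop_time


def write_series_csv(path: str | Path, series: ConcentrationSeries) -> Path:
    """Write a concentration series as ``time_min,value,analyte,units`` CSV."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_min": series.times_min,
            "value": series.values,
            "analyte": series.analyte_label,
            "units": series.units_label,
        }
    )
    # repr-based formatting so floats round-trip bit-exactly
    df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))
    return path


def read_series_csv(path: str | Path) -> ConcentrationSeries:
    """Read a concentration series CSV, validating the header strictly."""
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    if list(df.columns) != SERIES_CSV_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {SERIES_CSV_COLUMNS}, got {list(df.columns)}"
        )
    analytes = df["analyte"].unique()
    units = df["units"].unique()
    if len(analytes) != 1 or len(units) != 1:
        raise ValueError(f"{path}: analyte and units must be constant per file")
    return ConcentrationSeries(
        analyte_label=str(analytes[0]),
        times_min=df["time_min"].to_numpy(dtype=float),
        values=df["value"].to_numpy(dtype=float),
        units_label=str(units[0]),
    )


def frame_filename(index: int, t_min: float) -> str:
    """Canonical frame filename ``frame_<index>_<t_min>.png``."""
    return f"frame_{index:05d}_{float(t_min):g}.png"


def write_frames(directory: str | Path, series: FrameSeries) -> list[Path]:
    """Write every frame as an 8-bit grayscale PNG into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(series):
        p = directory / frame_filename(i, frame.timestamp_min)
        iio.imwrite(p, frame.pixels)
        paths.append(p)
    return paths


def read_frames(directory: str | Path) -> FrameSeries:
    """Read a frame directory back into a time-ordered FrameSeries.

    Filenames must follow :func:`frame_filename`; frames are ordered by
    index and timestamps are recovered from the filename.
    """
    directory = Path(directory)
    entries = []
    for p in directory.iterdir():
        m = _FRAME_RE.match(p.name)
        if m:
            entries.append((int(m.group(1)), float(m.group(2)), p))
    if not entries:
        raise ValueError(f"{directory}: no frame_<index>_<t_min>.png files found")
    entries.sort()
    frames = []
    for _, t, p in entries:
        pixels = np.asarray(iio.imread(p))
        frames.append(Frame(pixels=pixels.astype(np.uint8), timestamp_min=t))
    return FrameSeries(frames=frames)
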