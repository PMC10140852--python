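"""Plots: process-variable traces and lot-comparison concentration curves."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .endpoint import ConcentrationSeries, EndpointResult
from .monitor import ProcessTrace

__all__ = ["plot_trace", "plot_comparison"]


def plot_trace(
    trace: ProcessTrace,
    stop_time_min: Optional[float],
    path: str | Path,
) -> Path:
    """Plot raw and smoothed process variable vs time, marking the stop.

    Axes are minutes and percent of the 8-bit full scale; the stop marker is
    omitted when no stop occurred.  Rendering is deterministic for equal
    inputs (PNG metadata aside).
    """
    if len(trace) == 0:
        raise ValueError("cannot plot an empty trace")
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(trace.times_min, trace.raw_percent, color="0.6", lw=0.8, label="raw")
    ax.plot(
        trace.times_min, trace.smoothed_percent, color="tab:blue", lw=1.6,
        label="smoothed",
    )
    if stop_time_min is not None:
        ax.axvline(stop_time_min, color="tab:red", ls="--", lw=1.2,
                   label=f"stop at {stop_time_min:g} min")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("process variable (% of 255)")
    ax.set_title("ROI mean intensity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=110, metadata={"Software": None})
    plt.close(fig)
    return Path(path)


def plot_comparison(
    control: ConcentrationSeries,
    treatment: ConcentrationSeries,
    control_result: EndpointResult,
    treatment_result: EndpointResult,
    path: str | Path,
) -> Path:
    """Plot both lots' concentration curves with their detected endpoints."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for series, result, color, name in (
        (control, control_result, "tab:orange", "control"),
        (treatment, treatment_result, "tab:green", "treatment"),
    ):
        ax.plot(series.times_min, series.values, "o-", ms=3, lw=1.2,
                color=color, label=f"{name} ({series.analyte_label})")
        if result.found:
            ax.axvline(result.endpoint_time_min, color=color, ls="--", lw=1.1,
                       label=f"{name} endpoint {result.endpoint_time_min:g} min")
    ax.set_xlabel("time (min)")
    unit = control.units_label or "a.u."
    ax.set_ylabel(f"concentration ({unit})")
    ax.set_title("Lot comparison: release curves and plateau endpoints")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110, metadata={"Software": None})
    plt.close(fig)
    return Path(path)
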