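"""Calibrated demonstration fixtures.

The benchtop experiments this package models reported two headline
comparisons:

* the image-based monitor stopped the control run at ~600 min and the
  vibrated run at ~420 min (a ~30 % time reduction);
* the spectrophotometric successive-differences endpoint fell at 630 min for
  the control lot and 450 min for the vibrated lot (a ~29 % reduction).

These fixtures reproduce those operating points synthetically.  The physical
free parameters the experiments never pinned down — the dye reservoir volume
driving the discoloration, and the release time constant of each lot — are
calibrated here by bisection so that the *actual* detector (the windowed
stopping rule, or the successive-differences scan) lands on the reported
endpoint times.  The reductions themselves are then computed by the
detectors, not assumed.

Calibration exploits monotonicity: the stop time grows with the reservoir
volume, and the plateau endpoint grows with the release time constant, so a
bisection over the free parameter converges onto the target grid time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .endpoint import ConcentrationSeries, EndpointCriteria, detect_endpoint
from .monitor import StoppingRule, replay_stop_rule, smooth_trace
from .phantom import DilutionModel, ReleaseModel, dye_concentration, transmittance

__all__ = [
    "CalibrationError",
    "MonitoredRun",
    "ideal_trace_percent",
    "stop_time_for_model",
    "calibrate_reservoir_volume",
    "monitored_run_fixture",
    "calibrate_release_time_constant",
    "lot_series_fixture",
    "DEMO_FRAME_INTERVAL_MIN",
    "DEMO_BACKLIGHT",
    "DEMO_OPTICAL_DEPTH",
    "CONTROL_PLATEAU_NG_ML",
    "TREATMENT_PLATEAU_NG_ML",
]


class CalibrationError(RuntimeError):
    """Raised when bisection cannot land the detector on the target time."""


# Demo operating point: 5-min frame cadence (the slower of the rig's two
# cadences), a 250/255 backlight and an initial optical depth eps_l*c0 = 2.5
# (initial transmittance ~0.3 %, comfortably in the sigmoid regime).
DEMO_FRAME_INTERVAL_MIN = 5.0
DEMO_BACKLIGHT = 250
DEMO_OPTICAL_DEPTH = 2.5

# Reported lot plateau levels (DNA, as printed for the two lots).
CONTROL_PLATEAU_NG_ML = 118.0
TREATMENT_PLATEAU_NG_ML = 79.0


@dataclass
class MonitoredRun:
    """A trace-level monitored run: times, raw/smoothed percent, stop time."""

    times_min: np.ndarray
    raw_percent: np.ndarray
    smoothed_percent: np.ndarray
    stop_time_min: Optional[float]
    model: DilutionModel


def ideal_trace_percent(
    model: DilutionModel,
    frame_interval_min: float,
    n_frames: int,
    backlight_intensity: int = DEMO_BACKLIGHT,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free process-variable trace of a discoloration run, in percent.

    Evaluates the Gompertz closed form
    ``I0 * 10**(-eps_l * c0 * exp(-Q t / 60 V)) / 255 * 100`` on the frame
    grid — exactly what the monitor would measure on noise-free frames,
    before 8-bit rounding.
    """
    times = np.arange(n_frames) * frame_interval_min
    conc = dye_concentration(model, times)
    intensity = backlight_intensity * transmittance(conc, model.optical_depth_coeff)
    return times, intensity / 255.0 * 100.0


def stop_time_for_model(
    model: DilutionModel,
    rule: StoppingRule,
    frame_interval_min: float,
    n_frames: int,
    backlight_intensity: int = DEMO_BACKLIGHT,
) -> Optional[float]:
    """Stop time of the windowed rule on the model's noise-free trace."""
    times, raw = ideal_trace_percent(
        model, frame_interval_min, n_frames, backlight_intensity
    )
    return replay_stop_rule(times, raw, rule)


def _bisect_to_grid_time(evaluate, lo: float, hi: float, target: float,
                         what: str, iters: int = 200) -> float:
    """Bisect a monotone parameter→grid-time map onto an exact target time.

    ``evaluate`` maps the free parameter to a detector time (``None`` when
    the detector never fires, treated as +inf).  The map is a nondecreasing
    step function quantized to the sampling grid, so some parameter interval
    maps exactly onto the target; bisection shrinks onto its boundary.
    """
    def f(x: float) -> float:
        t = evaluate(x)
        return math.inf if t is None else t

    f_lo, f_hi = f(lo), f(hi)
    if f_lo == target:
        return lo
    if f_hi == target:
        return hi
    if not (f_lo < target < f_hi):
        raise CalibrationError(
            f"{what}: target {target} min not bracketed "
            f"(f({lo})={f_lo}, f({hi})={f_hi})"
        )
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if f_mid == target:
            return mid
        if f_mid < target:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"{what}: bisection failed to land on {target} min "
        f"(bracket [{lo}, {hi}] -> [{f(lo)}, {f(hi)}])"
    )


def calibrate_reservoir_volume(
    target_stop_min: float,
    rule: StoppingRule = StoppingRule(),
    frame_interval_min: float = DEMO_FRAME_INTERVAL_MIN,
    flow_rate_mL_per_h: float = 50.0,
    optical_depth_coeff: float = DEMO_OPTICAL_DEPTH,
    backlight_intensity: int = DEMO_BACKLIGHT,
) -> DilutionModel:
    """Find the reservoir volume whose run stops exactly at ``target_stop_min``.

    All other physics is held at the demo operating point; the volume is the
    one free parameter the experiments left unreported.
    """
    n_frames = int(target_stop_min / frame_interval_min * 1.5) + rule.window_n

    def evaluate(volume: float) -> Optional[float]:
        model = DilutionModel(
            reservoir_volume_mL=volume,
            flow_rate_mL_per_h=flow_rate_mL_per_h,
            initial_concentration=1.0,
            optical_depth_coeff=optical_depth_coeff,
        )
        return stop_time_for_model(
            model, rule, frame_interval_min, n_frames, backlight_intensity
        )

    volume = _bisect_to_grid_time(
        evaluate, lo=1.0, hi=2000.0, target=float(target_stop_min),
        what="reservoir volume calibration",
    )
    return DilutionModel(
        reservoir_volume_mL=volume,
        flow_rate_mL_per_h=flow_rate_mL_per_h,
        initial_concentration=1.0,
        optical_depth_coeff=optical_depth_coeff,
    )


def monitored_run_fixture(
    target_stop_min: float,
    rule: StoppingRule = StoppingRule(),
    frame_interval_min: float = DEMO_FRAME_INTERVAL_MIN,
    backlight_intensity: int = DEMO_BACKLIGHT,
) -> MonitoredRun:
    """Build a noise-free monitored run whose rule fires at the target time."""
    model = calibrate_reservoir_volume(
        target_stop_min,
        rule=rule,
        frame_interval_min=frame_interval_min,
        backlight_intensity=backlight_intensity,
    )
    n_frames = int(target_stop_min / frame_interval_min * 1.5) + rule.window_n
    times, raw = ideal_trace_percent(
        model, frame_interval_min, n_frames, backlight_intensity
    )
    stop = replay_stop_rule(times, raw, rule)
    if stop != target_stop_min:
        raise CalibrationError(
            f"calibrated run stopped at {stop} min, expected {target_stop_min}"
        )
    keep = times <= stop
    return MonitoredRun(
        times_min=times[keep],
        raw_percent=raw[keep],
        smoothed_percent=smooth_trace(raw[keep], rule.smoothing_sigma),
        stop_time_min=stop,
        model=model,
    )


def calibrate_release_time_constant(
    target_endpoint_min: float,
    plateau_concentration: float,
    criteria: EndpointCriteria = EndpointCriteria(),
    interval_min: float = 30.0,
    duration_min: float = 720.0,
    analyte_label: str = "dna",
) -> ReleaseModel:
    """Find the release time constant whose noise-free plateau endpoint lands
    exactly at ``target_endpoint_min`` on the sampling grid."""

    times = np.arange(0.0, duration_min + interval_min / 2.0, interval_min)

    def evaluate(tau: float) -> Optional[float]:
        values = plateau_concentration * (1.0 - np.exp(-times / tau))
        series = ConcentrationSeries(
            analyte_label=analyte_label, times_min=times, values=values
        )
        return detect_endpoint(series, criteria).endpoint_time_min

    tau = _bisect_to_grid_time(
        evaluate, lo=5.0, hi=duration_min, target=float(target_endpoint_min),
        what="release time-constant calibration",
    )
    return ReleaseModel(
        plateau_concentration=plateau_concentration,
        time_constant_min=tau,
        noise_sd=0.0,
        analyte_label=analyte_label,
    )


def lot_series_fixture(
    control_endpoint_min: float = 630.0,
    treatment_endpoint_min: float = 450.0,
    criteria: EndpointCriteria = EndpointCriteria(),
    interval_min: float = 30.0,
    duration_min: float = 720.0,
) -> tuple[ConcentrationSeries, ConcentrationSeries]:
    """Control/treatment DNA release series with calibrated plateau onsets.

    The control lot (slower kinetics, higher plateau: 118 ng/mL) reaches its
    plateau at ``control_endpoint_min``; the vibrated treatment lot (faster
    kinetics, lower plateau: 79 ng/mL) at ``treatment_endpoint_min``.
    """
    series = []
    for target, plateau in (
        (control_endpoint_min, CONTROL_PLATEAU_NG_ML),
        (treatment_endpoint_min, TREATMENT_PLATEAU_NG_ML),
    ):
        model = calibrate_release_time_constant(
            target, plateau, criteria=criteria,
            interval_min=interval_min, duration_min=duration_min,
        )
        times = np.arange(0.0, duration_min + interval_min / 2.0, interval_min)
        values = model.plateau_concentration * (
            1.0 - np.exp(-times / model.time_constant_min)
        )
        series.append(
            ConcentrationSeries(
                analyte_label="dna",
                times_min=times,
                values=values,
                units_label="ng/mL",
            )
        )
    return series[0], series[1]
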