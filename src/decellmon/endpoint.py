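"""Plateau endpoint detection for spectrophotometric concentration series.

During perfusion decellularization, DNA and protein released from the tissue
accumulate in the chamber fluid; once the tissue is fully decellularized the
measured concentrations become stationary.  The endpoint is detected by the
method of successive differences: scan the absolute differences between
consecutive samples for a sustained fall below a small threshold, and report
the moment the concentration curve enters its plateau.

The threshold is expressed relative to the full range of the series (default
2 %), which makes detection invariant to the measurement scale, and a short
run of consecutive small differences (default 3) is required so a single
flat step in an otherwise changing series does not trigger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ConcentrationSeries",
    "EndpointCriteria",
    "EndpointResult",
    "LotComparison",
    "EndpointNotFoundError",
    "successive_differences",
    "detect_endpoint",
    "percent_reduction",
    "compare_lots",
]

ANALYTE_LABELS = ("dye", "dna", "protein")


class EndpointNotFoundError(RuntimeError):
    """Raised when a series shows no concentration plateau."""


@dataclass
class ConcentrationSeries:
    """Sampled analyte concentrations over time.

    ``units_label`` is free text (e.g. ``"ng/uL"`` for nucleic acids,
    ``"mg/mL"`` for proteins) carried verbatim from the instrument output;
    no unit conversion is ever applied.
    """

    analyte_label: str
    times_min: np.ndarray
    values: np.ndarray
    units_label: str = ""

    def __post_init__(self) -> None:
        if self.analyte_label not in ANALYTE_LABELS:
            raise ValueError(
                f"analyte_label must be one of {ANALYTE_LABELS}, got {self.analyte_label!r}"
            )
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_min.shape != self.values.shape or self.times_min.ndim != 1:
            raise ValueError("times_min and values must be equal-length 1-D sequences")
        if self.times_min.size > 1 and np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times_min must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("concentration values must be >= 0")

    def __len__(self) -> int:
        return len(self.times_min)


@dataclass(frozen=True)
class EndpointCriteria:
    """Successive-differences plateau criteria.

    ``diff_epsilon`` is a fraction of the series' full range (max - min);
    ``run_length_m`` consecutive differences must all fall at or below the
    resulting absolute threshold for the plateau to be declared.
    """

    diff_epsilon: float = 0.02
    run_length_m: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.diff_epsilon < 1:
            raise ValueError(
                f"diff_epsilon must lie in (0, 1), got {self.diff_epsilon}"
            )
        if self.run_length_m < 1:
            raise ValueError(f"run_length_m must be >= 1, got {self.run_length_m}")


@dataclass
class EndpointResult:
    """Detected plateau onset for one concentration series."""

    endpoint_time_min: Optional[float]
    diffs: np.ndarray
    criteria_used: EndpointCriteria
    flat_series: bool = False

    @property
    def found(self) -> bool:
        return self.endpoint_time_min is not None


@dataclass(frozen=True)
class LotComparison:
    """Control-vs-treatment endpoint times and the relative time saving."""

    t_control_min: float
    t_treatment_min: float
    percent_reduction: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "percent_reduction",
            percent_reduction(self.t_control_min, self.t_treatment_min),
        )


def successive_differences(series: ConcentrationSeries) -> np.ndarray:
    """Absolute differences between consecutive measurements.

    ``d_i = |v_i - v_{i-1}|`` for ``i = 1..n-1``; requires at least two
    samples.  Absolute values make the scan robust to small non-monotone
    noise near the plateau.
    """
    if len(series) < 2:
        raise ValueError("successive differences require at least 2 samples")
    return np.abs(np.diff(series.values))


def detect_endpoint(
    series: ConcentrationSeries, criteria: EndpointCriteria = EndpointCriteria()
) -> EndpointResult:
    """Locate the plateau onset via the successive-differences method.

    With ``eps_abs = diff_epsilon * (max - min)`` of the series, the endpoint
    is the time of sample ``i`` where ``i`` is the smallest index such that
    the ``run_length_m`` differences ``d_i .. d_{i+m-1}`` are all
    ``<= eps_abs`` — the first sample at which the curve has entered its
    plateau.  Returns ``endpoint_time_min = None`` when no qualifying run
    exists.  A degenerate, perfectly flat series (max == min) reports its
    first sample with the ``flat_series`` diagnostic set.
    """
    m = criteria.run_length_m
    if len(series) < m + 1:
        raise ValueError(
            f"need at least run_length_m + 1 = {m + 1} samples, got {len(series)}"
        )
    diffs = successive_differences(series)
    vrange = float(series.values.max() - series.values.min())
    if vrange == 0.0:
        return EndpointResult(
            endpoint_time_min=float(series.times_min[0]),
            diffs=diffs,
            criteria_used=criteria,
            flat_series=True,
        )
    eps_abs = criteria.diff_epsilon * vrange
    ok = diffs <= eps_abs
    # diffs[j] is d_{j+1}: the change arriving at sample j+1.
    for j in range(len(diffs) - m + 1):
        if ok[j : j + m].all():
            return EndpointResult(
                endpoint_time_min=float(series.times_min[j + 1]),
                diffs=diffs,
                criteria_used=criteria,
            )
    return EndpointResult(endpoint_time_min=None, diffs=diffs, criteria_used=criteria)


def percent_reduction(t_control_min: float, t_treatment_min: float) -> float:
    """Relative time saving of the treatment over the control, in percent.

    ``(t_control - t_treatment) / t_control * 100`` at full precision;
    rounding to a whole percent is a presentation step left to callers.
    """
    if t_control_min <= 0:
        raise ValueError(f"t_control_min must be > 0, got {t_control_min}")
    if t_treatment_min < 0:
        raise ValueError(f"t_treatment_min must be >= 0, got {t_treatment_min}")
    return (t_control_min - t_treatment_min) / t_control_min * 100.0


def compare_lots(
    control: ConcentrationSeries,
    treatment: ConcentrationSeries,
    criteria: EndpointCriteria = EndpointCriteria(),
) -> LotComparison:
    """Detect both lots' endpoints and compute the percent time reduction.

    Raises :class:`EndpointNotFoundError` naming the offending lot when
    either series shows no plateau.
    """
    results = {}
    for name, series in (("control", control), ("treatment", treatment)):
        res = detect_endpoint(series, criteria)
        if not res.found:
            raise EndpointNotFoundError(
                f"no plateau detected in the {name} lot "
                f"({series.analyte_label} series, n={len(series)})"
            )
        results[name] = res.endpoint_time_min
    return LotComparison(
        t_control_min=results["control"], t_treatment_min=results["treatment"]
    )
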