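"""Synthetic optical phantom for decellularization monitoring.

Emulates the benchtop "simulated heart" rig: a dye-filled elastic phantom
backlit by a green LED panel, perfused with distilled water at constant flow
so the dye washes out, and photographed by a fixed camera.  Three physical
ingredients drive the model:

* **Well-stirred dilution** — the dye reservoir (volume ``V`` mL, stirred)
  is fed water at ``Q`` mL/h, so the dye concentration decays as
  ``c(t) = c0 * exp(-Q t / (60 V))`` with ``t`` in minutes.
* **Beer–Lambert optics** — transmitted backlight fraction is
  ``T = 10**(-eps_l * c)`` where ``eps_l`` lumps molar absorptivity and path
  length per unit concentration.  The in-phantom pixel intensity is
  ``I0 * T``; the composition of the two exponentials makes the monitored
  intensity trace a Gompertz (S-shaped) curve.
* **Saturating release kinetics** — cellular material (DNA, protein, or dye)
  released into the chamber accumulates as ``C(t) = C_inf * (1 - exp(-t/tau))``,
  reaching a stationary plateau; samples are drawn on a fixed grid
  (every 30 min by default) with additive, zero-truncated Gaussian noise.

Everything is seeded and reproducible, so downstream monitoring and endpoint
detection can be tested end to end without hardware.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .endpoint import ConcentrationSeries
from .monitor import Frame, FrameSeries

__all__ = [
    "DilutionModel",
    "ReleaseModel",
    "PhantomScene",
    "dye_concentration",
    "transmittance",
    "render_frame",
    "simulate_discoloration_run",
    "release_concentration",
    "simulate_sampling",
]

ANALYTE_LABELS = ("dye", "dna", "protein")


@dataclass(frozen=True)
class DilutionModel:
    """Well-stirred single-compartment dye dilution under constant flow.

    Attributes
    ----------
    reservoir_volume_mL
        Stirred dye reservoir volume V (mL).
    flow_rate_mL_per_h
        Distilled-water flow Q (mL/h); the rig's clinical syringe pump runs
        at 50 mL/h.
    initial_concentration
        Dye concentration c0 at t = 0, arbitrary units.
    optical_depth_coeff
        Lumped ε·l per unit concentration, so absorbance A = eps_l * c.
    """

    reservoir_volume_mL: float
    flow_rate_mL_per_h: float = 50.0
    initial_concentration: float = 1.0
    optical_depth_coeff: float = 2.5

    def __post_init__(self) -> None:
        for name in ("reservoir_volume_mL", "flow_rate_mL_per_h", "initial_concentration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.optical_depth_coeff < 0:
            raise ValueError(
                f"optical_depth_coeff must be >= 0, got {self.optical_depth_coeff}"
            )

    @property
    def time_constant_min(self) -> float:
        """Dilution time constant 60·V/Q in minutes."""
        return 60.0 * self.reservoir_volume_mL / self.flow_rate_mL_per_h


@dataclass(frozen=True)
class ReleaseModel:
    """Saturating (first-order) analyte release into the chamber."""

    plateau_concentration: float
    time_constant_min: float
    noise_sd: float = 0.0
    analyte_label: str = "dye"

    def __post_init__(self) -> None:
        if self.plateau_concentration <= 0:
            raise ValueError(
                f"plateau_concentration must be > 0, got {self.plateau_concentration}"
            )
        if self.time_constant_min <= 0:
            raise ValueError(
                f"time_constant_min must be > 0, got {self.time_constant_min}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.analyte_label not in ANALYTE_LABELS:
            raise ValueError(
                f"analyte_label must be one of {ANALYTE_LABELS}, got {self.analyte_label!r}"
            )


@dataclass(frozen=True)
class PhantomScene:
    """Camera/scene geometry for rendering phantom frames.

    The heart phantom is an axis-aligned ellipse (pixel coordinates) lying
    fully inside the frame; the default frame size matches the rig camera's
    1024 × 768 resolution.  ``backlight_intensity`` is the incident intensity
    I0 seen through a fully cleared phantom.
    """

    width_px: int = 1024
    height_px: int = 768
    center_x: float = 512.0
    center_y: float = 384.0
    semi_axis_x: float = 280.0
    semi_axis_y: float = 220.0
    backlight_intensity: int = 250
    background_intensity: int = 30
    pixel_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.semi_axis_x <= 0 or self.semi_axis_y <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        if not (
            self.semi_axis_x <= self.center_x <= self.width_px - self.semi_axis_x
            and self.semi_axis_y <= self.center_y <= self.height_px - self.semi_axis_y
        ):
            raise ValueError("heart ellipse must lie fully within the frame")
        for name in ("backlight_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must lie in [0, 255], got {v}")
        if self.pixel_noise_sd < 0:
            raise ValueError(f"pixel_noise_sd must be >= 0, got {self.pixel_noise_sd}")

    def heart_mask(self) -> np.ndarray:
        """Boolean mask of pixels inside the heart ellipse."""
        yy, xx = np.mgrid[0 : self.height_px, 0 : self.width_px]
        return (
            ((xx - self.center_x) / self.semi_axis_x) ** 2
            + ((yy - self.center_y) / self.semi_axis_y) ** 2
        ) <= 1.0

    def bounding_roi(self) -> tuple[int, int, int, int]:
        """Tight half-open bounding box (x0, y0, x1, y1) of the ellipse."""
        x0 = int(np.floor(self.center_x - self.semi_axis_x))
        x1 = int(np.ceil(self.center_x + self.semi_axis_x))
        y0 = int(np.floor(self.center_y - self.semi_axis_y))
        y1 = int(np.ceil(self.center_y + self.semi_axis_y))
        return x0, y0, x1, y1


def dye_concentration(model: DilutionModel, t_min) -> np.ndarray | float:
    """Dye concentration at time ``t_min`` under well-stirred dilution.

    ``c(t) = c0 * exp(-Q t / (60 V))``; strictly decreasing for Q > 0,
    with half-life ``60 V ln 2 / Q`` minutes.
    """
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_min must be >= 0")
    c = model.initial_concentration * np.exp(-t / model.time_constant_min)
    return float(c) if np.isscalar(t_min) else c


def transmittance(concentration, optical_depth_coeff) -> np.ndarray | float:
    """Beer–Lambert transmitted fraction ``T = 10**(-eps_l * c)``.

    Absorbance is linear in concentration, so T lies in (0, 1] and decreases
    monotonically with concentration.
    """
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    if optical_depth_coeff < 0:
        raise ValueError("optical_depth_coeff must be >= 0")
    t = 10.0 ** (-optical_depth_coeff * c)
    return float(t) if np.isscalar(concentration) else t


def render_frame(
    scene: PhantomScene,
    concentration: float,
    optical_depth_coeff: float,
    rng: Optional[np.random.Generator] = None,
    timestamp_min: float = 0.0,
    _mask: Optional[np.ndarray] = None,
) -> Frame:
    """Render one 8-bit grayscale frame of the backlit phantom.

    Pixels inside the heart ellipse take ``round(I0 * T)`` plus optional
    Gaussian noise; background pixels take ``background_intensity`` plus the
    same noise; everything is clipped to [0, 255].  With
    ``pixel_noise_sd = 0`` the rendering is exactly deterministic.
    """
    mask = scene.heart_mask() if _mask is None else _mask
    inside = float(
        np.round(scene.backlight_intensity * transmittance(concentration, optical_depth_coeff))
    )
    img = np.where(mask, inside, float(scene.background_intensity))
    if scene.pixel_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(scene.seed)
        img = img + rng.normal(0.0, scene.pixel_noise_sd, size=img.shape)
        img = np.round(img)
    pixels = np.clip(img, 0, 255).astype(np.uint8)
    return Frame(pixels=pixels, timestamp_min=timestamp_min)


def simulate_discoloration_run(
    scene: PhantomScene,
    model: DilutionModel,
    frame_interval_min: float,
    max_frames: int,
) -> tuple[FrameSeries, pd.DataFrame]:
    """Simulate a full discoloration run.

    Frames are timestamped at ``i * frame_interval_min``.  Alongside the
    frames, a ground-truth log records the true dye concentration and the
    noise-free, unrounded in-region mean intensity
    ``I0 * 10**(-eps_l * c0 * exp(-Q t / 60 V))`` — a Gompertz curve — for
    per-frame oracle checks.

    Returns
    -------
    (FrameSeries, DataFrame)
        The frame series and a log with columns ``time_min``,
        ``concentration`` and ``ideal_mean_intensity``.
    """
    if frame_interval_min <= 0:
        raise ValueError(f"frame_interval_min must be > 0, got {frame_interval_min}")
    if max_frames <= 0:
        raise ValueError(f"max_frames must be > 0, got {max_frames}")
    rng = np.random.default_rng(scene.seed)
    mask = scene.heart_mask()
    eps_l = model.optical_depth_coeff
    frames = []
    records = []
    for i in range(max_frames):
        t = i * frame_interval_min
        c = dye_concentration(model, t)
        frames.append(
            render_frame(scene, c, eps_l, rng=rng, timestamp_min=t, _mask=mask)
        )
        records.append(
            {
                "time_min": t,
                "concentration": c,
                "ideal_mean_intensity": scene.backlight_intensity
                * transmittance(c, eps_l),
            }
        )
    return FrameSeries(frames=frames), pd.DataFrame.from_records(records)


def release_concentration(model: ReleaseModel, t_min) -> np.ndarray | float:
    """Analyte concentration ``C(t) = C_inf * (1 - exp(-t/tau))``.

    Monotone increasing from 0 toward the plateau ``C_inf``; at ``t = tau``
    the curve sits at ``(1 - 1/e) ≈ 0.632`` of the plateau.
    """
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_min must be >= 0")
    c = model.plateau_concentration * (1.0 - np.exp(-t / model.time_constant_min))
    return float(c) if np.isscalar(t_min) else c


def simulate_sampling(
    model: ReleaseModel,
    duration_min: float,
    interval_min: float = 30.0,
    seed: int = 0,
    units_label: str = "",
) -> ConcentrationSeries:
    """Simulate periodic chamber sampling of a released analyte.

    Samples are taken at ``0, interval, 2*interval, ...`` up to and including
    ``duration_min`` (emulating the rig's 30 µL draws every 30 min), with
    additive Gaussian noise of standard deviation ``model.noise_sd``
    truncated at zero (concentrations cannot be negative).
    """
    if interval_min <= 0:
        raise ValueError(f"interval_min must be > 0, got {interval_min}")
    if duration_min < interval_min:
        raise ValueError("duration_min must be at least one interval")
    times = np.arange(0.0, duration_min + interval_min / 2.0, interval_min)
    values = np.asarray(release_concentration(model, times), dtype=float)
    if model.noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, model.noise_sd, size=values.shape)
        values = np.maximum(values, 0.0)
    return ConcentrationSeries(
        analyte_label=model.analyte_label,
        times_min=times,
        values=values,
        units_label=units_label,
    )
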