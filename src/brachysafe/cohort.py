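"""Synthetic patient cohort and phantom-measurement emulation.

Stands in for clinical inputs: patients are drawn with water-equivalent
thicknesses and total implant strength from truncated-at-zero normal
distributions (defaults match the 21-patient study summary statistics),
and phantom measurement sessions are emulated by adding background,
multiplicative statistical noise and detector range clipping to a
simulated depth series.

Everything here is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import truncnorm

from .assess import (
    DIRECTIONS,
    PatientGeometry,
    SourceImplant,
    predict_h10_rate,
)
from .physics import DecayData, decay_factor
from .transport import DepthDoseSeries

__all__ = [
    "CohortSpec",
    "MeasurementEmulatorSpec",
    "generate_cohort",
    "emulate_measurement",
    "subtract_background",
    "generate_phantom_sessions",
    "emulate_patient_measurements",
]

# study-cohort defaults: per-direction WET mean/SD (cm) and implant Sk (U)
_DEFAULT_WET = {
    "anterior": (10.33, 1.42),
    "posterior": (10.41, 0.92),
    "left": (17.19, 1.51),
    "right": (17.24, 1.53),
}
_DEFAULT_SK = (35.15, 8.73)


@dataclass(frozen=True)
class CohortSpec:
    """Sampling parameters for a synthetic implant cohort."""

    n_patients: int = 21
    wet_mean_sd_cm: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_WET)
    )
    sk_mean_sd_U: tuple[float, float] = _DEFAULT_SK
    dose_rate_constant_cGy_h_U: float = 0.954
    cf_Sv_Gy: float = 1.00
    wet_measurement_noise_cm: float = 0.0  # optional additive sigma, ~0.15 cm

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        for mean, sd in list(self.wet_mean_sd_cm.values()) + [self.sk_mean_sd_U]:
            if mean <= 0 or sd < 0:
                raise ValueError("means must be positive and SDs non-negative")


@dataclass(frozen=True)
class MeasurementEmulatorSpec:
    """Detector/measurement characteristics for emulated readings."""

    background_uSv_h: float = 0.20
    rel_noise: float = 0.02
    range_min_uSv_h: float = 5e-5  # 50 nSv/h
    range_max_uSv_h: float = 1e7  # 10 Sv/h
    sessions: int = 9
    session_interval_days: float = 7.0

    def __post_init__(self) -> None:
        if self.background_uSv_h < 0 or self.rel_noise < 0:
            raise ValueError("background and noise must be non-negative")
        if self.range_min_uSv_h >= self.range_max_uSv_h:
            raise ValueError("detector range minimum must be below maximum")


def _truncated_normal(
    mean: float, sd: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Normal(mean, sd) truncated at zero; degenerate at the mean for sd=0."""
    if sd == 0:
        return np.full(n, mean)
    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def generate_cohort(
    spec: CohortSpec, seed: int
) -> list[tuple[PatientGeometry, SourceImplant]]:
    """Draw a reproducible synthetic cohort of (geometry, implant) pairs."""
    rng = np.random.default_rng(seed)
    n = spec.n_patients
    wets = {}
    for direction in DIRECTIONS:
        mean, sd = spec.wet_mean_sd_cm[direction]
        w = _truncated_normal(mean, sd, n, rng)
        if spec.wet_measurement_noise_cm > 0:
            w = np.clip(
                w + rng.normal(0.0, spec.wet_measurement_noise_cm, n), 1e-6, None
            )
        wets[direction] = w
    sk = _truncated_normal(*spec.sk_mean_sd_U, n, rng)
    out = []
    for i in range(n):
        geometry = PatientGeometry(
            anterior_cm=float(wets["anterior"][i]),
            posterior_cm=float(wets["posterior"][i]),
            left_cm=float(wets["left"][i]),
            right_cm=float(wets["right"][i]),
        )
        implant = SourceImplant(
            sk_U=float(sk[i]),
            dose_rate_constant_cGy_h_U=spec.dose_rate_constant_cGy_h_U,
            cf_Sv_Gy=spec.cf_Sv_Gy,
        )
        out.append((geometry, implant))
    return out


def emulate_measurement(
    true_rate_uSv_h: float | np.ndarray,
    spec: MeasurementEmulatorSpec,
    rng: np.random.Generator,
):
    """Detector reading for a true rate: background + noise + range clipping."""
    rate = np.asarray(true_rate_uSv_h, float)
    if np.any(rate < 0):
        raise ValueError("true rate must be non-negative")
    reading = rate + spec.background_uSv_h
    if spec.rel_noise > 0:
        reading = reading * (1.0 + rng.normal(0.0, spec.rel_noise, reading.shape))
    reading = np.clip(reading, spec.range_min_uSv_h, spec.range_max_uSv_h)
    return float(reading) if np.isscalar(true_rate_uSv_h) else reading


def subtract_background(measured_uSv_h, spec: MeasurementEmulatorSpec):
    """Invert the background step of :func:`emulate_measurement`."""
    return np.asarray(measured_uSv_h, float) - spec.background_uSv_h


def generate_phantom_sessions(
    series: DepthDoseSeries,
    spec: MeasurementEmulatorSpec,
    seed: int,
    decay: DecayData | None = None,
    decay_enabled: bool = True,
) -> list[np.ndarray]:
    """Emulate weekly repeat measurements of a simulated depth series.

    Session ``i`` (0-based) is decay-corrected by ``i`` inter-session
    intervals and passed through the measurement emulator; returns one
    array of measured rates per session (same order as the series depths).
    Series values are taken as already being in uSv/h scale units.
    """
    rng = np.random.default_rng(seed)
    decay = decay or DecayData()
    base = series.values
    sessions = []
    for i in range(spec.sessions):
        factor = (
            decay_factor(decay, i * spec.session_interval_days)
            if decay_enabled
            else 1.0
        )
        sessions.append(np.asarray(emulate_measurement(base * factor, spec, rng)))
    return sessions


def emulate_patient_measurements(
    cohort: Sequence[tuple[PatientGeometry, SourceImplant]],
    seed: int,
    distances_cm: Sequence[float] = (0.0, 30.0, 100.0),
    surface_bias: float = -0.10,
    far_bias: float = 0.0,
    rel_noise: float = 0.05,
) -> list[dict]:
    """Synthetic 'measured' external rates for a cohort.

    Applies the predictive model, a configurable multiplicative bias
    (default -10% at the body surface, none farther out) and multiplicative
    Gaussian noise — enough structure for end-to-end validation exercises
    without clinical data.  Returns one record per
    (patient, direction, distance).
    """
    rng = np.random.default_rng(seed)
    records = []
    for pid, (geometry, implant) in enumerate(cohort):
        for direction in DIRECTIONS:
            z = geometry.wet(direction)
            for d in distances_cm:
                predicted = predict_h10_rate(implant, z, d)
                bias = surface_bias if d == 0.0 else far_bias
                measured = predicted * (1.0 + bias) * (
                    1.0 + rng.normal(0.0, rel_noise)
                )
                records.append(
                    {
                        "patient_id": pid,
                        "direction": direction,
                        "distance_cm": d,
                        "predicted_uSv_h": predicted,
                        "measured_uSv_h": max(measured, 0.0),
                    }
                )
    return records
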