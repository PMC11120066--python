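"""Absolute dose-rate prediction and radiation-safety assessment.

The predictive model scales a normalized exponential depth model by the
implant source term::

    H*(10) [uSv/h] = Sk [U] * Lambda [cGy/h/U] * 1e4 [uGy/cGy] * CF [Sv/Gy]
                     * A * exp(-b * z)

with ``z`` the water-equivalent thickness from the implant centre to the
body surface in a given direction, and (A, b) taken per detector-distance
class from the published registry (or from a user-fitted model).  On top of
that sit the far-field approximation (inverse square law plus a 2 cm
water-equivalent half-value layer), cumulative-dose integration over
radioactive decay, the regulatory release check (5 mSv/year caregivers,
1 mSv/year public, inclusive boundary), and the uncertainty-budget
arithmetic (quadrature combination, weighted consensus of dose-rate
constants).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from types import MappingProxyType
from typing import Iterable, Mapping, Sequence

from .expmodel import ExponentialModel, REFERENCE_MODELS, evaluate_model
from .physics import DecayData, decay_factor

__all__ = [
    "DIRECTIONS",
    "SourceImplant",
    "PatientGeometry",
    "DosePrediction",
    "ExposureScenario",
    "RegulatoryLimit",
    "ReleaseCheck",
    "UncertaintyBudget",
    "USV_PER_CGY",
    "predict_h10_rate",
    "predict_patient",
    "far_field_rate",
    "cumulative_dose",
    "check_release",
    "combine_quadrature",
    "consensus_lambda",
]

DIRECTIONS = ("anterior", "posterior", "left", "right")

#: 1 cGy = 1e4 uGy; multiplied by CF (Sv/Gy) this turns cGy/h into uSv/h.
USV_PER_CGY = 1.0e4

#: Default water-equivalent half-value layer for far-field estimates (cm).
DEFAULT_HVL_CM = 2.0


@dataclass(frozen=True)
class SourceImplant:
    """Total implanted source term at the implant date."""

    sk_U: float
    dose_rate_constant_cGy_h_U: float = 0.954
    cf_Sv_Gy: float = 1.00
    implant_date: date | None = None

    def __post_init__(self) -> None:
        if self.sk_U < 0:
            raise ValueError("air-kerma strength must be non-negative")
        if self.dose_rate_constant_cGy_h_U <= 0 or self.cf_Sv_Gy <= 0:
            raise ValueError("dose-rate constant and CF must be positive")


@dataclass(frozen=True)
class PatientGeometry:
    """Water-equivalent thickness (cm) from implant centre to body surface."""

    anterior_cm: float
    posterior_cm: float
    left_cm: float
    right_cm: float

    def __post_init__(self) -> None:
        if min(self.anterior_cm, self.posterior_cm, self.left_cm, self.right_cm) <= 0:
            raise ValueError("all water-equivalent thicknesses must be positive")

    def wet(self, direction: str) -> float:
        return getattr(self, f"{direction}_cm")


@dataclass(frozen=True)
class DosePrediction:
    direction: str
    distance_cm: float
    h10_uSv_h: float
    eval_date: date | None = None

    def __post_init__(self) -> None:
        if self.h10_uSv_h < 0:
            raise ValueError("predicted rate must be non-negative")


@dataclass(frozen=True)
class ExposureScenario:
    """Occupancy pattern of one person near the patient."""

    category: str = "caregiver"
    distance_cm: float = 100.0
    daily_hours: float = 24.0
    occupancy: float = 1.0
    horizon_days: float = math.inf

    def __post_init__(self) -> None:
        if not 0 <= self.occupancy <= 1:
            raise ValueError("occupancy factor must lie in [0, 1]")
        if not 0 <= self.daily_hours <= 24:
            raise ValueError("daily exposure must lie in [0, 24] hours")
        if self.horizon_days < 0:
            raise ValueError("horizon must be non-negative")


class RegulatoryLimit:
    """Annual effective-dose limits (mSv/year) by person category."""

    DEFAULTS: Mapping[str, float] = MappingProxyType({"caregiver": 5.0, "public": 1.0})

    @classmethod
    def annual_mSv(cls, category: str) -> float:
        try:
            return cls.DEFAULTS[category]
        except KeyError:
            raise ValueError(f"unknown person category {category!r}") from None


@dataclass(frozen=True)
class ReleaseCheck:
    category: str
    annual_dose_mSv: float
    limit_mSv: float
    compliant: bool
    margin_mSv: float


@dataclass(frozen=True)
class UncertaintyBudget:
    """Named relative uncertainty components, percent at one sigma."""

    components: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.components.values()):
            raise ValueError("uncertainty components must be non-negative")


def predict_h10_rate(
    implant: SourceImplant,
    z_cm: float,
    distance_cm: float,
    models: Mapping[float, ExponentialModel] = REFERENCE_MODELS,
) -> float:
    """Predicted H*(10) rate (uSv/h) at a detector-distance class.

    ``z_cm`` is the water-equivalent depth of the implant centre.  The
    normalized model for ``distance_cm`` is scaled by
    ``Sk * Lambda * CF`` converted to uSv/h.
    """
    if z_cm <= 0:
        raise ValueError("water-equivalent depth must be positive")
    try:
        model = models[distance_cm]
    except KeyError:
        raise ValueError(
            f"no model registered for distance {distance_cm} cm"
        ) from None
    prefactor = (
        implant.sk_U
        * implant.dose_rate_constant_cGy_h_U
        * USV_PER_CGY
        * implant.cf_Sv_Gy
    )
    return prefactor * evaluate_model(model, z_cm)


def predict_patient(
    implant: SourceImplant,
    patient: PatientGeometry,
    eval_date: date | None = None,
    decay: DecayData | None = None,
    models: Mapping[float, ExponentialModel] = REFERENCE_MODELS,
    distances_cm: Sequence[float] = (0.0, 30.0, 100.0),
) -> list[DosePrediction]:
    """Predictions for the four directions at each distance class.

    If ``eval_date`` and the implant date are given, the source term is
    decay-corrected to the evaluation date.
    """
    factor = 1.0
    if eval_date is not None:
        if implant.implant_date is None:
            raise ValueError("implant date required for decay correction")
        elapsed = (eval_date - implant.implant_date).days
        factor = decay_factor(decay or DecayData(), elapsed)
    out = []
    for direction in DIRECTIONS:
        z = patient.wet(direction)
        for d in distances_cm:
            rate = factor * predict_h10_rate(implant, z, d, models)
            out.append(
                DosePrediction(
                    direction=direction, distance_cm=d, h10_uSv_h=rate,
                    eval_date=eval_date,
                )
            )
    return out


def far_field_rate(
    reference_rate_uSv_h: float,
    reference_distance_cm: float,
    target_distance_cm: float,
    extra_wet_cm: float = 0.0,
    hvl_cm: float = DEFAULT_HVL_CM,
) -> float:
    """Far-field estimate: inverse square law plus half-value-layer attenuation.

    Valid beyond roughly three times the implant extent, where the implant
    acts as a point source at its geometric centre.
    """
    if reference_distance_cm <= 0 or target_distance_cm <= 0:
        raise ValueError("distances must be positive")
    return (
        reference_rate_uSv_h
        * (reference_distance_cm / target_distance_cm) ** 2
        * 0.5 ** (extra_wet_cm / hvl_cm)
    )


def cumulative_dose(
    initial_rate_uSv_h: float,
    scenario: ExposureScenario,
    decay: DecayData | None = None,
) -> float:
    """Time-integrated dose (mSv) under exponential source decay.

    ``rate * f * (1 - exp(-lambda T)) / lambda`` with occupancy fraction
    ``f = daily_hours / 24 * occupancy``; an infinite horizon gives
    ``rate * f * T_half / ln 2``.
    """
    if initial_rate_uSv_h < 0:
        raise ValueError("initial rate must be non-negative")
    decay = decay or DecayData()
    lam = decay.decay_constant_per_day
    f = scenario.daily_hours / 24.0 * scenario.occupancy
    rate_per_day = initial_rate_uSv_h * 24.0
    if math.isinf(scenario.horizon_days):
        integral = 1.0 / lam
    else:
        integral = (1.0 - math.exp(-lam * scenario.horizon_days)) / lam
    return rate_per_day * f * integral / 1000.0


def check_release(annual_dose_mSv: float, category: str) -> ReleaseCheck:
    """Compare an annual dose with the category limit (inclusive boundary)."""
    if annual_dose_mSv < 0:
        raise ValueError("dose must be non-negative")
    limit = RegulatoryLimit.annual_mSv(category)
    return ReleaseCheck(
        category=category,
        annual_dose_mSv=annual_dose_mSv,
        limit_mSv=limit,
        compliant=annual_dose_mSv <= limit,
        margin_mSv=limit - annual_dose_mSv,
    )


def combine_quadrature(budget: UncertaintyBudget | Mapping[str, float]) -> float:
    """Quadrature (root-sum-square) combination of percent components."""
    comps = budget.components if isinstance(budget, UncertaintyBudget) else budget
    if not comps:
        raise ValueError("uncertainty budget is empty")
    return math.sqrt(sum(v**2 for v in comps.values()))


def consensus_lambda(values: Iterable[tuple[float, float]]) -> float:
    """Weighted average of dose-rate-constant determinations."""
    pairs = list(values)
    if not pairs:
        raise ValueError("no values supplied")
    if any(w < 0 for _, w in pairs):
        raise ValueError("weights must be non-negative")
    total_w = sum(w for _, w in pairs)
    if total_w == 0:
        raise ValueError("at least one weight must be positive")
    return sum(v * w for v, w in pairs) / total_w
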