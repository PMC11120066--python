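"""Depth-series normalization and exponential model fitting.

A depth-dose series is normalized to its value at a reference source depth
(1 cm by default, each detector-distance series to its own reference) and
fitted with ``A * exp(-b z)`` by nonlinear least squares on the linear
scale, initialized from the log-linear regression solution.  R^2 is
reported on the untransformed scale.

``REFERENCE_MODELS`` holds the published coefficient sets for the three
detector distances (0, 30 and 100 cm), stored to four decimals exactly as
printed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .transport import DepthDoseSeries

__all__ = [
    "NormalizedSeries",
    "ExponentialModel",
    "REFERENCE_MODELS",
    "normalize_series",
    "fit_exponential",
    "evaluate_model",
    "r_squared",
    "half_value_layer",
]


@dataclass(frozen=True)
class NormalizedSeries:
    """Dimensionless depth series, unity at the reference depth."""

    distance_cm: float
    depths: tuple[float, ...]
    values: tuple[float, ...]
    reference_depth_cm: float = 1.0
    weights: tuple[float, ...] | None = None  # optional 1/sigma fit weights

    def __post_init__(self) -> None:
        if len(self.depths) != len(self.values):
            raise ValueError("depths and values must have equal length")
        i = self.depths.index(self.reference_depth_cm)
        if abs(self.values[i] - 1.0) > 1e-12:
            raise ValueError("value at the reference depth must be 1")


@dataclass(frozen=True)
class ExponentialModel:
    """``A * exp(-b z)`` with goodness of fit, per detector distance."""

    amplitude: float
    decay_per_cm: float
    distance_cm: float
    r2: float | None = None
    n_points: int | None = None
    reference_depth_cm: float | None = None

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.decay_per_cm < 0:
            raise ValueError("decay constant must be non-negative")
        if self.r2 is not None and not 0 <= self.r2 <= 1:
            raise ValueError("R^2 must lie in [0, 1]")

    def __call__(self, z) -> float | np.ndarray:
        return evaluate_model(self, z)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "distance_cm": self.distance_cm,
            "A": self.amplitude,
            "b_per_cm": self.decay_per_cm,
            "r2": self.r2,
            "n_points": self.n_points,
            "reference_depth_cm": self.reference_depth_cm,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "ExponentialModel":
        d = json.loads(Path(path).read_text())
        return cls(
            amplitude=d["A"],
            decay_per_cm=d["b_per_cm"],
            distance_cm=d["distance_cm"],
            r2=d.get("r2"),
            n_points=d.get("n_points"),
            reference_depth_cm=d.get("reference_depth_cm"),
        )


#: Published normalized-model coefficients, keyed by detector distance (cm).
REFERENCE_MODELS: Mapping[float, ExponentialModel] = MappingProxyType(
    {
        0.0: ExponentialModel(amplitude=1.7811, decay_per_cm=0.5841, distance_cm=0.0),
        30.0: ExponentialModel(amplitude=1.4360, decay_per_cm=0.3555, distance_cm=30.0),
        100.0: ExponentialModel(amplitude=1.4026, decay_per_cm=0.3273, distance_cm=100.0),
    }
)


def normalize_series(
    series: DepthDoseSeries, reference_depth_cm: float = 1.0
) -> NormalizedSeries:
    """Divide a depth series by its value at ``reference_depth_cm``."""
    depths = [float(z) for z in series.depths]
    values = np.asarray(series.values, float)
    try:
        i = depths.index(float(reference_depth_cm))
    except ValueError:
        raise ValueError(
            f"reference depth {reference_depth_cm} cm not present in series"
        ) from None
    ref = values[i]
    if ref <= 0:
        raise ValueError("value at the reference depth must be positive")
    rel_se = np.asarray(series.rel_ses, float)
    norm = values / ref
    norm[i] = 1.0  # exact by construction
    weights = tuple(
        1.0 / max(se * v, 1e-300) for se, v in zip(rel_se, norm)
    )
    return NormalizedSeries(
        distance_cm=series.distance_cm,
        depths=tuple(depths),
        values=tuple(float(v) for v in norm),
        reference_depth_cm=float(reference_depth_cm),
        weights=weights,
    )


def r_squared(observed, fitted) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``."""
    obs = np.asarray(observed, float)
    fit = np.asarray(fitted, float)
    if obs.shape != fit.shape or obs.size < 2:
        raise ValueError("observed and fitted must have equal length >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero total variance: R^2 undefined")
    ss_res = float(np.sum((obs - fit) ** 2))
    return 1.0 - ss_res / ss_tot


def fit_exponential(series: NormalizedSeries, weighted: bool = False) -> ExponentialModel:
    """Least-squares ``A * exp(-b z)`` fit on the linear scale.

    Initial values come from the closed-form log-linear regression.  With
    ``weighted=True`` the stored 1/sigma weights (from the tally SEs) are
    used; the default is an unweighted fit.
    """
    z = np.asarray(series.depths, float)
    y = np.asarray(series.values, float)
    if z.size < 3:
        raise ValueError("need at least 3 points to fit")
    if np.any(y <= 0):
        raise ValueError("all values must be positive")
    if np.allclose(y, y[0]):
        raise ValueError("degenerate (constant) series")
    slope, intercept = np.polyfit(z, np.log(y), 1)
    p0 = (math.exp(intercept), -slope if slope < 0 else 1e-6)
    sigma = None
    if weighted and series.weights is not None:
        sigma = 1.0 / np.asarray(series.weights, float)
    popt, _ = curve_fit(
        lambda x, a, b: a * np.exp(-b * x), z, y, p0=p0, sigma=sigma, maxfev=20_000
    )
    a, b = float(popt[0]), float(popt[1])
    r2 = r_squared(y, a * np.exp(-b * z))
    return ExponentialModel(
        amplitude=a,
        decay_per_cm=b,
        distance_cm=series.distance_cm,
        r2=min(max(r2, 0.0), 1.0),
        n_points=int(z.size),
        reference_depth_cm=series.reference_depth_cm,
    )


def evaluate_model(model: ExponentialModel, z):
    """``A * exp(-b z)`` at water-equivalent depth ``z`` (cm), z >= 0."""
    zz = np.asarray(z, float)
    if np.any(zz < 0):
        raise ValueError("depth must be non-negative")
    out = model.amplitude * np.exp(-model.decay_per_cm * zz)
    return float(out) if np.isscalar(z) else out


def half_value_layer(model: ExponentialModel) -> float:
    """Water-equivalent thickness halving the rate: ``ln 2 / b`` (cm)."""
    if model.decay_per_cm <= 0:
        raise ValueError("decay constant must be positive")
    return math.log(2) / model.decay_per_cm
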