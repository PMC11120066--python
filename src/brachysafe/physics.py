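"""Embedded physical data and interpolation services.

Ships small versioned CSV fixtures (photon emission lines of I-125,
water/air photon interaction coefficients for 5-60 keV, and operational
ambient-dose-equivalent conversion coefficients for 10-60 keV) together
with the interpolation rules used everywhere else in the package:

* attenuation coefficients are interpolated log-log (exact at grid nodes);
* the air-kerma -> H*(10) conversion is interpolated linearly in energy;
* the fluence -> H*(10) conversion is interpolated log-log.

No extrapolation is performed anywhere: energies outside a table's grid
raise :class:`EnergyOutOfRangeError`.  Safety-relevant code fails loudly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EnergyOutOfRangeError",
    "EmissionSpectrum",
    "AttenuationTable",
    "ConversionCurve",
    "DecayData",
    "I125_HALF_LIFE_DAYS",
    "load_spectrum",
    "load_attenuation",
    "load_conversion",
    "interpolate_mu",
    "kerma_to_h10",
    "fluence_to_h10",
    "mean_energy",
    "decay_factor",
]

#: Half-life of I-125 in days (standard consensus value; configurable via
#: :class:`DecayData`).
I125_HALF_LIFE_DAYS = 59.4

_MU_COMPONENTS = ("total", "photoelectric", "incoherent", "coherent")


class EnergyOutOfRangeError(ValueError):
    """Requested energy lies outside the tabulated grid (no extrapolation)."""


@dataclass(frozen=True)
class EmissionSpectrum:
    """Discrete photon emission lines: (energy keV, photons per decay)."""

    lines: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.lines:
            raise ValueError("spectrum must contain at least one line")
        energies = [e for e, _ in self.lines]
        if any(e <= 0 for e in energies):
            raise ValueError("all line energies must be positive")
        if any(i <= 0 for _, i in self.lines):
            raise ValueError("all line intensities must be positive")
        if energies != sorted(energies):
            raise ValueError("lines must be sorted ascending by energy")

    @property
    def energies(self) -> np.ndarray:
        return np.array([e for e, _ in self.lines])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([i for _, i in self.lines])


@dataclass(frozen=True)
class AttenuationTable:
    """Linear photon interaction coefficients on an ascending energy grid.

    Coefficients are in 1/cm at the stated density.  ``total`` includes the
    coherent contribution and equals the sum of the three partials at every
    node (enforced at load time within 0.5%).
    """

    material: str
    energy_keV: np.ndarray
    mu_total: np.ndarray
    mu_photoelectric: np.ndarray
    mu_incoherent: np.ndarray
    mu_coherent: np.ndarray
    density_g_cm3: float

    def __post_init__(self) -> None:
        grid = np.asarray(self.energy_keV, float)
        if not np.all(np.diff(grid) > 0):
            raise ValueError("energy grid must be strictly ascending")
        partial_sum = self.mu_photoelectric + self.mu_incoherent + self.mu_coherent
        if not np.allclose(partial_sum, self.mu_total, rtol=5e-3):
            raise ValueError("partial coefficients must sum to total within 0.5%")
        for comp in _MU_COMPONENTS[1:]:
            if np.any(self._component(comp) > self.mu_total * (1 + 1e-12)):
                raise ValueError(f"{comp} coefficient exceeds total")

    def _component(self, component: str) -> np.ndarray:
        try:
            return getattr(self, f"mu_{component}")
        except AttributeError:
            raise ValueError(f"unknown component {component!r}") from None

    def mu(self, energy_keV, component: str = "total") -> np.ndarray | float:
        """Log-log interpolated linear coefficient (1/cm); exact at nodes."""
        if component not in _MU_COMPONENTS:
            raise ValueError(f"unknown component {component!r}")
        e = np.asarray(energy_keV, float)
        _check_range(e, self.energy_keV, f"attenuation[{self.material}]")
        values = self._component(component)
        out = np.exp(
            np.interp(np.log(e), np.log(self.energy_keV), np.log(values))
        )
        return float(out) if np.isscalar(energy_keV) else out


@dataclass(frozen=True)
class ConversionCurve:
    """Energy-dependent conversion coefficients to ambient dose equivalent.

    ``kind`` is either ``"fluence_to_h10"`` (pSv cm^2, log-log interpolation)
    or ``"kerma_to_h10"`` (Sv/Gy, linear-in-energy interpolation).
    """

    kind: str
    energy_keV: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.energy_keV, float)
        if not np.all(np.diff(grid) > 0):
            raise ValueError("energy grid must be strictly ascending")
        if np.any(self.coefficients < 0):
            raise ValueError("conversion coefficients must be non-negative")

    def __call__(self, energy_keV) -> np.ndarray | float:
        e = np.asarray(energy_keV, float)
        _check_range(e, self.energy_keV, self.kind)
        if self.kind == "fluence_to_h10":
            out = np.exp(
                np.interp(np.log(e), np.log(self.energy_keV), np.log(self.coefficients))
            )
        else:
            out = np.interp(e, self.energy_keV, self.coefficients)
        return float(out) if np.isscalar(energy_keV) else out

    @property
    def min_energy_keV(self) -> float:
        return float(self.energy_keV[0])


@dataclass(frozen=True)
class DecayData:
    """Radioactive decay bookkeeping for a single nuclide."""

    half_life_days: float = I125_HALF_LIFE_DAYS

    def __post_init__(self) -> None:
        if self.half_life_days <= 0:
            raise ValueError("half-life must be positive")

    @property
    def decay_constant_per_day(self) -> float:
        return math.log(2) / self.half_life_days


def _check_range(e: np.ndarray, grid: np.ndarray, label: str) -> None:
    if np.any(e < grid[0]) or np.any(e > grid[-1]):
        raise EnergyOutOfRangeError(
            f"energy outside {label} grid [{grid[0]:g}, {grid[-1]:g}] keV"
        )


# ---------------------------------------------------------------------------
# embedded-data loaders


def _data_path(name: str) -> Path:
    return Path(str(resources.files("brachysafe").joinpath("data", name)))


def _read_csv(path: Path) -> tuple[dict[str, str], np.ndarray, list[str]]:
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    header: list[str] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
            continue
        if not header:
            header = line.split(",")
            continue
        rows.append([float(x) for x in line.split(",")])
    return meta, np.array(rows), header


def load_spectrum(path: str | Path | None = None) -> EmissionSpectrum:
    """Load the embedded bare-source I-125 spectrum (or an override file)."""
    p = Path(path) if path is not None else _data_path("spectrum_i125.csv")
    _, rows, _ = _read_csv(p)
    return EmissionSpectrum(tuple((float(e), float(i)) for e, i in rows))


def load_attenuation(material: str = "water", path: str | Path | None = None) -> AttenuationTable:
    """Load embedded interaction coefficients for ``water`` or ``air``."""
    p = Path(path) if path is not None else _data_path(f"attenuation_{material}.csv")
    meta, rows, _ = _read_csv(p)
    return AttenuationTable(
        material=meta.get("material", material),
        energy_keV=rows[:, 0],
        mu_total=rows[:, 1],
        mu_photoelectric=rows[:, 2],
        mu_incoherent=rows[:, 3],
        mu_coherent=rows[:, 4],
        density_g_cm3=float(meta.get("density_g_cm3", "nan")),
    )


def load_conversion(kind: str = "kerma_to_h10", path: str | Path | None = None) -> ConversionCurve:
    """Load an embedded conversion curve: ``kerma_to_h10`` or ``fluence_to_h10``."""
    if kind not in ("kerma_to_h10", "fluence_to_h10"):
        raise ValueError(f"unknown conversion kind {kind!r}")
    name = "conv_kerma_h10.csv" if kind == "kerma_to_h10" else "conv_fluence_h10.csv"
    p = Path(path) if path is not None else _data_path(name)
    _, rows, _ = _read_csv(p)
    return ConversionCurve(kind=kind, energy_keV=rows[:, 0], coefficients=rows[:, 1])


# ---------------------------------------------------------------------------
# operations


def interpolate_mu(table: AttenuationTable, energy_keV, component: str = "total"):
    """Linear attenuation coefficient (1/cm) at ``energy_keV``, log-log."""
    return table.mu(energy_keV, component)


def kerma_to_h10(curve: ConversionCurve, energy_keV):
    """Air-kerma -> H*(10) conversion factor (Sv/Gy) at ``energy_keV``."""
    if curve.kind != "kerma_to_h10":
        raise ValueError("curve is not an air-kerma conversion")
    return curve(energy_keV)


def fluence_to_h10(curve: ConversionCurve, energy_keV):
    """Fluence -> H*(10) conversion coefficient (pSv cm^2) at ``energy_keV``."""
    if curve.kind != "fluence_to_h10":
        raise ValueError("curve is not a fluence conversion")
    return curve(energy_keV)


def mean_energy(spectrum: EmissionSpectrum) -> float:
    """Intensity-weighted mean photon energy (keV)."""
    w = spectrum.intensities
    return float(np.sum(spectrum.energies * w) / np.sum(w))


def decay_factor(decay: DecayData, elapsed_days: float) -> float:
    """Fraction of activity remaining after ``elapsed_days`` >= 0."""
    if elapsed_days < 0:
        raise ValueError("elapsed time must be non-negative")
    return math.exp(-decay.decay_constant_per_day * elapsed_days)
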