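"""Simplified analog Monte Carlo photon transport in a window water phantom.

A point isotropic source of I-125 photons sits at depth ``z`` behind the
centre of the thin entrance window of a rectangular water phantom.  Ambient
dose equivalent H*(10) per decay is tallied at point detectors in air on the
source axis, at configurable distances from the phantom surface, using a
next-event (expected-value, point-detector) estimator scored at the emission
vertex and at every interaction vertex.

Physics model (documented approximations):

* free-electron Klein-Nishina incoherent scattering (no scattering
  function, no Doppler broadening);
* coherent scattering as a direction change without energy loss with an
  isotropic angular distribution (toggleable);
* implicit capture: at each collision the statistical weight is multiplied
  by the scattering probability, with Russian roulette below a weight
  threshold;
* the thin entrance window and source tube are treated as water; air
  attenuation between phantom surface and detector is neglected
  (< 0.5% over 100 cm at these energies);
* photons below the fluence-conversion grid minimum (10 keV) contribute no
  H*(10); transport continues down to the 5 keV cutoff.

Fluence at the detector is converted to H*(10) with the embedded
fluence -> ambient-dose-equivalent coefficients, giving pSv per decay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .physics import (
    AttenuationTable,
    ConversionCurve,
    EmissionSpectrum,
    load_attenuation,
    load_conversion,
    load_spectrum,
)

__all__ = [
    "PhantomGeometry",
    "DetectorPoint",
    "DETECTOR_STANDOFF_CM",
    "PhotonState",
    "TallyResult",
    "DepthDoseSeries",
    "TransportPhysics",
    "sample_emission",
    "compton_scatter",
    "klein_nishina_differential",
    "klein_nishina_total",
    "next_event_contribution",
    "simulate_h10",
    "simulate_h10_multi",
    "simulate_depth_series",
    "simulate_depth_series_multi",
]

_R_E_CM = 2.8179403262e-13  # classical electron radius
_MEC2_KEV = 511.0
FOUR_PI = 4.0 * math.pi


@dataclass(frozen=True)
class PhantomGeometry:
    """Rectangular water phantom with a thin entrance window.

    The phantom occupies ``x in [-W/2, W/2]``, ``y in [-H/2, H/2]``,
    ``z in [0, D]``; the window is centred on the ``z = 0`` face and the
    source sits on the axis at ``(0, 0, source_depth_cm)``.
    """

    width_cm: float = 35.0
    height_cm: float = 35.0
    depth_cm: float = 37.0
    window_thickness_mm: float = 0.254
    window_size_cm: float = 27.0
    source_depth_cm: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.source_depth_cm < self.depth_cm:
            raise ValueError("source depth must lie strictly inside the phantom")
        if self.window_size_cm >= min(self.width_cm, self.height_cm):
            raise ValueError("window must be smaller than the phantom face")

    @property
    def source_position(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.source_depth_cm])


#: Effective centre of the survey-meter sensitive volume behind its front
#: face (cm).  A reading "at 0 cm" means the housing touches the phantom;
#: the tally point sits this far behind the contact plane.
DETECTOR_STANDOFF_CM = 4.5


@dataclass(frozen=True)
class DetectorPoint:
    """Point detector in air on the source axis, outside the phantom.

    ``distance_cm`` is the nominal front-face distance from the phantom
    surface; ``standoff_cm`` adds the instrument's effective-centre depth,
    so the tally point lies at ``distance_cm + standoff_cm``.
    """

    distance_cm: float
    medium: str = "air"
    standoff_cm: float = 0.0

    def __post_init__(self) -> None:
        if self.distance_cm < 0 or self.standoff_cm < 0:
            raise ValueError("detector distances must be non-negative")

    @property
    def position(self) -> np.ndarray:
        return np.array([0.0, 0.0, -(self.distance_cm + self.standoff_cm)])


@dataclass
class PhotonState:
    """Single in-flight photon (used at API edges; transport is vectorised)."""

    position: np.ndarray
    direction: np.ndarray
    energy_keV: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if not 0 < self.weight <= 1:
            raise ValueError("weight must lie in (0, 1]")


@dataclass(frozen=True)
class TallyResult:
    """H*(10) per decay at one detector with its statistical error."""

    h10_per_decay_pSv: float
    rel_se: float
    n_histories: int
    seed: int
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.h10_per_decay_pSv < 0 or self.rel_se < 0:
            raise ValueError("tally value and relative SE must be non-negative")


@dataclass(frozen=True)
class DepthDoseSeries:
    """H*(10) per decay versus source depth at one detector distance."""

    distance_cm: float
    points: tuple[tuple[float, TallyResult], ...]

    def __post_init__(self) -> None:
        depths = [z for z, _ in self.points]
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValueError("depths must be strictly ascending")
        for (_, a), (_, b) in zip(self.points, self.points[1:]):
            tol = 3.0 * math.hypot(
                a.rel_se * a.h10_per_decay_pSv, b.rel_se * b.h10_per_decay_pSv
            )
            if b.h10_per_decay_pSv >= a.h10_per_decay_pSv + tol:
                raise ValueError(
                    "tally values must decrease with depth (within 3 combined SE)"
                )

    @property
    def depths(self) -> np.ndarray:
        return np.array([z for z, _ in self.points])

    @property
    def values(self) -> np.ndarray:
        return np.array([t.h10_per_decay_pSv for _, t in self.points])

    @property
    def rel_ses(self) -> np.ndarray:
        return np.array([t.rel_se for _, t in self.points])

    def to_records(self) -> list[dict]:
        return [
            {
                "distance_cm": self.distance_cm,
                "depth_cm": z,
                "h10_per_decay_pSv": t.h10_per_decay_pSv,
                "rel_se": t.rel_se,
                "n_histories": t.n_histories,
                "seed": t.seed,
            }
            for z, t in self.points
        ]


@dataclass(frozen=True)
class TransportPhysics:
    """Bundle of physical data and transport options.

    ``attenuation=None`` switches the medium to vacuum (no collisions, no
    attenuation) — used by the inverse-square oracle tests.
    """

    spectrum: EmissionSpectrum
    attenuation: AttenuationTable | None
    fluence_curve: ConversionCurve
    cutoff_keV: float = 5.0
    scatter_enabled: bool = True
    rayleigh_enabled: bool = True
    max_scatter_order: int = 10
    roulette_weight: float = 1e-4
    roulette_survival: float = 0.1

    @classmethod
    def default(cls, **overrides) -> "TransportPhysics":
        return cls(
            spectrum=load_spectrum(),
            attenuation=load_attenuation("water"),
            fluence_curve=load_conversion("fluence_to_h10"),
            **overrides,
        )


# ---------------------------------------------------------------------------
# elementary sampling / kernels


def _isotropic_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    cos_t = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * math.pi, n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def sample_emission(spectrum: EmissionSpectrum, rng: np.random.Generator, n: int | None = None):
    """Draw (energy, direction) from the source term.

    Energies are drawn with probability proportional to line intensity and
    directions isotropically on the sphere.  With ``n=None`` a single
    (float, 3-vector) pair is returned, otherwise arrays of shape (n,) and
    (n, 3).
    """
    m = 1 if n is None else n
    p = spectrum.intensities / spectrum.intensities.sum()
    energies = rng.choice(spectrum.energies, size=m, p=p)
    directions = _isotropic_directions(rng, m)
    if n is None:
        return float(energies[0]), directions[0]
    return energies, directions


def klein_nishina_differential(energy_keV, cos_theta):
    """Free-electron Klein-Nishina d(sigma)/d(Omega) in cm^2/sr per electron."""
    a = np.asarray(energy_keV, float) / _MEC2_KEV
    c = np.asarray(cos_theta, float)
    k = 1.0 / (1.0 + a * (1.0 - c))
    return 0.5 * _R_E_CM**2 * k**2 * (k + 1.0 / k - (1.0 - c**2))


def klein_nishina_total(energy_keV):
    """Free-electron Klein-Nishina total cross-section in cm^2 per electron."""
    a = np.asarray(energy_keV, float) / _MEC2_KEV
    t1 = (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - np.log(1 + 2 * a) / a)
    t2 = np.log(1 + 2 * a) / (2 * a)
    t3 = (1 + 3 * a) / (1 + 2 * a) ** 2
    out = 2 * np.pi * _R_E_CM**2 * (t1 + t2 - t3)
    return float(out) if np.isscalar(energy_keV) else out


def compton_energy(energy_keV, cos_theta):
    """Scattered photon energy from the Compton relation."""
    a = np.asarray(energy_keV, float) / _MEC2_KEV
    return np.asarray(energy_keV, float) / (1.0 + a * (1.0 - np.asarray(cos_theta, float)))


def compton_scatter(energy_keV, rng: np.random.Generator, n: int | None = None):
    """Sample incoherent scattering: (scattered energy keV, polar angle rad).

    The polar angle follows the free-electron Klein-Nishina differential
    cross-section (rejection sampling against a flat envelope in cos(theta),
    which bounds the forward maximum for all energies); the energy follows
    the Compton relation at the sampled angle.
    """
    m = 1 if n is None else n
    e = np.broadcast_to(np.asarray(energy_keV, float), (m,)).copy()
    f_max = klein_nishina_differential(e, 1.0)
    cos_t = np.empty(m)
    todo = np.ones(m, bool)
    while todo.any():
        k = int(todo.sum())
        cand = rng.uniform(-1.0, 1.0, k)
        accept = rng.uniform(0.0, 1.0, k) * f_max[todo] <= klein_nishina_differential(
            e[todo], cand
        )
        idx = np.flatnonzero(todo)[accept]
        cos_t[idx] = cand[accept]
        todo[idx] = False
    e_out = compton_energy(e, cos_t)
    theta = np.arccos(np.clip(cos_t, -1.0, 1.0))
    if n is None:
        return float(e_out[0]), float(theta[0])
    return e_out, theta


def _rotate_directions(d: np.ndarray, cos_t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rotate unit vectors ``d`` by polar angle arccos(cos_t), uniform azimuth."""
    n = d.shape[0]
    phi = rng.uniform(0.0, 2.0 * math.pi, n)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
    # orthonormal frame around d; guard the pole
    helper = np.zeros_like(d)
    pole = np.abs(d[:, 2]) > 0.99
    helper[~pole, 2] = 1.0
    helper[pole, 0] = 1.0
    u = np.cross(helper, d)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(d, u)
    out = (
        d * cos_t[:, None]
        + u * (sin_t * np.cos(phi))[:, None]
        + v * (sin_t * np.sin(phi))[:, None]
    )
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _exit_distance(pos: np.ndarray, direction: np.ndarray, geom: PhantomGeometry) -> np.ndarray:
    """Distance from interior points to the box boundary along ``direction``."""
    lo = np.array([-geom.width_cm / 2, -geom.height_cm / 2, 0.0])
    hi = np.array([geom.width_cm / 2, geom.height_cm / 2, geom.depth_cm])
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo - pos) / direction
        t2 = (hi - pos) / direction
    t_far = np.where(direction != 0.0, np.maximum(t1, t2), np.inf)
    return t_far.min(axis=1)


# ---------------------------------------------------------------------------
# next-event estimator


def _fluence_coefficient(curve: ConversionCurve, energy: np.ndarray) -> np.ndarray:
    """Conversion coefficient with zero below the grid floor (no H*(10))."""
    e = np.asarray(energy, float)
    out = np.zeros_like(e)
    ok = e >= curve.min_energy_keV
    if ok.any():
        out[ok] = curve(e[ok])
    return out


def _next_event(
    pos: np.ndarray,
    energy: np.ndarray,
    weight: np.ndarray,
    pdf_per_sr,
    det_pos: np.ndarray,
    geom: PhantomGeometry,
    physics: TransportPhysics,
    energy_at_detector: np.ndarray | None = None,
) -> np.ndarray:
    """Expected H*(10) contribution (pSv) of each vertex to one detector."""
    delta = det_pos[None, :] - pos
    r = np.linalg.norm(delta, axis=1)
    if np.any(r <= 0):
        raise ValueError("vertex coincides with the detector point")
    direction = delta / r[:, None]
    e_det = energy if energy_at_detector is None else energy_at_detector
    if physics.attenuation is None:
        transmission = np.ones_like(r)
    else:
        path = np.minimum(_exit_distance(pos, direction, geom), r)
        mu = physics.attenuation.mu(e_det, "total")
        transmission = np.exp(-np.asarray(mu) * path)
    conv = _fluence_coefficient(physics.fluence_curve, e_det)
    return weight * pdf_per_sr * transmission * conv / r**2


def next_event_contribution(
    point: np.ndarray,
    energy_keV: float,
    detector: DetectorPoint,
    geometry: PhantomGeometry,
    physics: TransportPhysics,
) -> float:
    """Expected H*(10) (pSv per history) at ``detector`` from an isotropic
    emission vertex at ``point`` inside the phantom."""
    pos = np.asarray(point, float).reshape(1, 3)
    out = _next_event(
        pos,
        np.array([energy_keV]),
        np.ones(1),
        1.0 / FOUR_PI,
        detector.position,
        geometry,
        physics,
    )
    return float(out[0])


# ---------------------------------------------------------------------------
# history transport


def _run_batch(
    geom: PhantomGeometry,
    det_positions: np.ndarray,
    physics: TransportPhysics,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Transport ``n`` histories; return per-history tallies (n, n_det) pSv."""
    n_det = det_positions.shape[0]
    tally = np.zeros((n, n_det))
    energy, direction = sample_emission(physics.spectrum, rng, n)
    pos = np.broadcast_to(geom.source_position, (n, 3)).copy()
    weight = np.ones(n)
    idx = np.arange(n)

    for d in range(n_det):
        tally[:, d] += _next_event(
            pos, energy, weight, 1.0 / FOUR_PI, det_positions[d], geom, physics
        )
    if physics.attenuation is None or not physics.scatter_enabled:
        return tally

    att = physics.attenuation
    for _ in range(physics.max_scatter_order):
        if idx.size == 0:
            break
        mu_t = np.asarray(att.mu(energy, "total"))
        mu_inc = np.asarray(att.mu(energy, "incoherent"))
        mu_coh = (
            np.asarray(att.mu(energy, "coherent"))
            if physics.rayleigh_enabled
            else np.zeros_like(mu_t)
        )
        step = rng.exponential(1.0, idx.size) / mu_t
        inside = step < _exit_distance(pos, direction, geom)
        if not inside.any():
            break
        idx, pos, direction, energy, weight = (
            idx[inside],
            pos[inside] + step[inside, None] * direction[inside],
            direction[inside],
            energy[inside],
            weight[inside],
        )
        mu_t, mu_inc, mu_coh = mu_t[inside], mu_inc[inside], mu_coh[inside]

        # implicit capture
        weight = weight * (mu_inc + mu_coh) / mu_t
        is_compton = rng.uniform(0.0, 1.0, idx.size) * (mu_inc + mu_coh) < mu_inc

        # next-event at the collision vertex, per detector
        sigma = klein_nishina_total(energy)
        for d in range(n_det):
            delta = det_positions[d][None, :] - pos
            r = np.linalg.norm(delta, axis=1)
            cos_det = np.einsum("ij,ij->i", direction, delta) / r
            e_det = np.where(is_compton, compton_energy(energy, cos_det), energy)
            pdf = np.where(
                is_compton,
                klein_nishina_differential(energy, cos_det) / sigma,
                1.0 / FOUR_PI,
            )
            tally[idx, d] += _next_event(
                pos, energy, weight, pdf, det_positions[d], geom, physics,
                energy_at_detector=e_det,
            )

        # sample the actual outgoing state
        new_energy = energy.copy()
        cos_t = np.empty(idx.size)
        if is_compton.any():
            e_c, theta_c = compton_scatter(energy[is_compton], rng, int(is_compton.sum()))
            new_energy[is_compton] = e_c
            cos_t[is_compton] = np.cos(theta_c)
        if (~is_compton).any():
            cos_t[~is_compton] = rng.uniform(-1.0, 1.0, int((~is_compton).sum()))
        direction = _rotate_directions(direction, cos_t, rng)
        energy = new_energy

        alive = energy >= physics.cutoff_keV
        # Russian roulette on low weights
        low = alive & (weight < physics.roulette_weight)
        if low.any():
            survive = rng.uniform(0.0, 1.0, int(low.sum())) < physics.roulette_survival
            kill = np.flatnonzero(low)[~survive]
            alive[kill] = False
            boost = np.flatnonzero(low)[survive]
            weight[boost] /= physics.roulette_survival
        idx, pos, direction, energy, weight = (
            idx[alive],
            pos[alive],
            direction[alive],
            energy[alive],
            weight[alive],
        )
    return tally


def simulate_h10_multi(
    geometry: PhantomGeometry,
    detectors: Sequence[DetectorPoint],
    n_histories: int,
    seed: int,
    physics: TransportPhysics | None = None,
    rel_se_target: float = 0.03,
    batch_size: int = 50_000,
) -> list[TallyResult]:
    """Estimate H*(10) per decay at several detectors in one transport pass."""
    if n_histories < 1:
        raise ValueError("n_histories must be >= 1")
    physics = physics or TransportPhysics.default()
    det_positions = np.stack([d.position for d in detectors])
    rng = np.random.default_rng(seed)
    s1 = np.zeros(det_positions.shape[0])
    s2 = np.zeros(det_positions.shape[0])
    done = 0
    while done < n_histories:
        n = min(batch_size, n_histories - done)
        t = _run_batch(geometry, det_positions, physics, n, rng)
        s1 += t.sum(axis=0)
        s2 += (t**2).sum(axis=0)
        done += n
    mean = s1 / n_histories
    if n_histories > 1:
        var = np.maximum(s2 - s1**2 / n_histories, 0.0) / (n_histories - 1)
        se = np.sqrt(var / n_histories)
    else:
        se = np.zeros_like(mean)
    results = []
    for m, s in zip(mean, se):
        rel = float(s / m) if m > 0 else 0.0
        results.append(
            TallyResult(
                h10_per_decay_pSv=float(m),
                rel_se=rel,
                n_histories=n_histories,
                seed=seed,
                flagged=rel > rel_se_target,
            )
        )
    return results


def simulate_h10(
    geometry: PhantomGeometry,
    detector: DetectorPoint,
    n_histories: int,
    seed: int,
    physics: TransportPhysics | None = None,
    rel_se_target: float = 0.03,
    max_scatter_order: int | None = None,
) -> TallyResult:
    """Estimate H*(10) per decay (pSv) at a single detector.

    Deterministic for a given seed; the result is flagged (not rejected)
    when the relative standard error exceeds ``rel_se_target``.
    """
    if max_scatter_order is not None:
        physics = replace(
            physics or TransportPhysics.default(), max_scatter_order=max_scatter_order
        )
    return simulate_h10_multi(
        geometry, [detector], n_histories, seed, physics, rel_se_target
    )[0]


def simulate_depth_series(
    depths: Sequence[float],
    distance_cm: float,
    n_histories: int,
    seed: int,
    geometry: PhantomGeometry | None = None,
    physics: TransportPhysics | None = None,
    rel_se_target: float = 0.03,
) -> DepthDoseSeries:
    """Run one tally per source depth at a fixed detector distance."""
    series = simulate_depth_series_multi(
        depths, [distance_cm], n_histories, seed, geometry, physics, rel_se_target
    )
    return series[0]


def simulate_depth_series_multi(
    depths: Sequence[float],
    distances_cm: Sequence[float],
    n_histories: int,
    seed: int,
    geometry: PhantomGeometry | None = None,
    physics: TransportPhysics | None = None,
    rel_se_target: float = 0.03,
    standoff_cm: float = DETECTOR_STANDOFF_CM,
) -> list[DepthDoseSeries]:
    """Depth series at several detector distances sharing each transport pass.

    By default each detector is placed at its nominal distance plus the
    survey-meter effective-centre standoff (:data:`DETECTOR_STANDOFF_CM`),
    matching how the instrument was positioned in the measurements the
    depth models derive from; pass ``standoff_cm=0`` for bare points.
    """
    base = geometry or PhantomGeometry()
    physics = physics or TransportPhysics.default()
    detectors = [DetectorPoint(d, standoff_cm=standoff_cm) for d in distances_cm]
    child_seeds = np.random.SeedSequence(seed).spawn(len(depths))
    per_distance: list[list[tuple[float, TallyResult]]] = [[] for _ in distances_cm]
    for z, ss in zip(depths, child_seeds):
        geom = replace(base, source_depth_cm=float(z))
        sub_seed = int(ss.generate_state(1)[0])
        tallies = simulate_h10_multi(
            geom, detectors, n_histories, sub_seed, physics, rel_se_target
        )
        for i, t in enumerate(tallies):
            per_distance[i].append((float(z), t))
    return [
        DepthDoseSeries(distance_cm=float(d), points=tuple(pts))
        for d, pts in zip(distances_cm, per_distance)
    ]
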