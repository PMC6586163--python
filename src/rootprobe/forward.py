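"""Forward model of root pressure-probe experiments.

The composite transport model treats the root as an osmometer: the xylem
(pressurised, volume Vx) exchanges water across the root cylinder surface Ar
with hydraulic conductivity Lpr, while a permeating solute enters passively
with permeability Psr and is reflected with coefficient σsr ∈ [0, 1].  The
probe couples xylem volume to the measured root pressure through the elastic
coefficient β of the probe–root system (MPa m⁻³).

Two experiment types are modelled:

**Hydrostatic relaxation.**  A step offset ΔP₀ imposed with the probe's
micrometer screw relaxes mono-exponentially back to the steady-state pressure,

    P(t) = P_ss + ΔP₀ · exp(−kwr·t),      kwr = Lpr·Ar·β = ln 2 / t½w.

**Osmotic (biphasic) response.**  Raising the medium osmotic pressure by Δπ°s
first draws water out (fast water phase, rate kwr), then the permeating solute
follows (slow solute phase, rate ksr = Ar·Psr/Vx = ln 2 / t½s) and the
pressure recovers:

    P(t) = P₀ − σ·Δπ°s · kwr/(kwr−ksr) · (e^(−ksr·t) − e^(−kwr·t)).

The trace has a single interior minimum at tmin = ln(kwr/ksr)/(kwr−ksr), of
depth ΔPr, and the exact identity (ΔPr/Δπ°s)·e^(ksr·tmin) = σ holds — the
correction factor used when estimating reflection coefficients from measured
traces.  The degenerate case ksr → kwr is handled by the analytic limit
−σ·Δπ·kwr·t·e^(−kwr·t), not by perturbation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "TransportParams",
    "ProbeSystem",
    "RootGeometry",
    "PressureTrace",
    "hydrostatic_rate_constant",
    "solute_rate_constant",
    "xylem_volume",
    "simulate_hydrostatic_relaxation",
    "simulate_osmotic_response",
    "analytic_tmin",
    "analytic_delta_pr",
]

EventKind = Literal["hydrostatic_step", "osmotic_step", "cut"]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class TransportParams:
    """Transport triple of the root: (Lpr, Psr, σsr).

    Lpr : hydraulic conductivity, m s⁻¹ MPa⁻¹, > 0.
    Psr : solute permeability, m s⁻¹, ≥ 0 (0 = impermeant solute).
    sigma : reflection coefficient, dimensionless, in [0, 1].
    """

    Lpr: float
    Psr: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.Lpr <= 0:
            raise ValueError(f"Lpr must be > 0, got {self.Lpr}")
        if self.Psr < 0:
            raise ValueError(f"Psr must be ≥ 0, got {self.Psr}")
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError(f"sigma must lie in [0, 1], got {self.sigma}")


@dataclass(frozen=True)
class ProbeSystem:
    """Probe-side constants: elastic coefficient β and mounted root area Ar.

    beta : MPa m⁻³, pressure change per unit volume change of the probe–root
        system, > 0.
    Ar : m², surface area of the root segment mounted on the probe, > 0.
    """

    beta: float
    Ar: float

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.Ar <= 0:
            raise ValueError(f"Ar must be > 0, got {self.Ar}")


@dataclass(frozen=True)
class RootGeometry:
    """Geometry of the conductive root segment.

    The hydraulically non-conductive apical part (~15 mm from the tip) is
    excluded from the conductive length.  The functional xylem occupies a
    fixed fraction (default 1.5 %) of the conductive cylinder volume.
    """

    conductive_length: float  # m
    root_diameter: float  # m
    endodermis_radius: float  # m
    xylem_fraction: float = 0.015
    nonconductive_tip_length: float = 0.015  # m

    def __post_init__(self) -> None:
        if self.conductive_length <= 0:
            raise ValueError("conductive_length must be > 0")
        if self.root_diameter <= 0:
            raise ValueError("root_diameter must be > 0")
        if not 0.0 < self.xylem_fraction < 1.0:
            raise ValueError("xylem_fraction must lie in (0, 1)")
        if not 0.0 < self.endodermis_radius < self.root_diameter / 2:
            raise ValueError("endodermis_radius must lie in (0, root_diameter/2)")


@dataclass
class PressureTrace:
    """A time-stamped root-pressure series with its triggering event.

    ``time`` starts at 0 at the event sample and is strictly increasing;
    ``pressure`` is in MPa.  ``event_magnitude`` is the pressure offset ΔP₀
    for hydrostatic steps or the osmotic step Δπ°s for osmotic experiments.
    """

    time: np.ndarray
    pressure: np.ndarray
    event_kind: EventKind
    event_magnitude: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.time.shape != self.pressure.shape or self.time.ndim != 1:
            raise ValueError("time and pressure must be 1-D arrays of equal length")
        if self.time.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.pressure)):
            raise ValueError("pressures must be finite")

    @property
    def n(self) -> int:
        return int(self.time.size)

    def window(self, t_start: float, t_end: float) -> "PressureTrace":
        """Sub-trace with t_start ≤ t ≤ t_end (times are not re-based)."""
        mask = (self.time >= t_start) & (self.time <= t_end)
        if mask.sum() < 2:
            raise ValueError("window contains fewer than 2 samples")
        return PressureTrace(
            self.time[mask], self.pressure[mask], self.event_kind,
            self.event_magnitude, dict(self.meta),
        )


def hydrostatic_rate_constant(params: TransportParams, probe: ProbeSystem) -> float:
    """Rate constant of water exchange kwr = Lpr·Ar·β, s⁻¹ (t½w = ln 2/kwr)."""
    return params.Lpr * probe.Ar * probe.beta


def xylem_volume(geom: RootGeometry) -> float:
    """Functional xylem volume Vx = fraction × π (d/2)² L, m³."""
    radius = geom.root_diameter / 2.0
    return geom.xylem_fraction * math.pi * radius * radius * geom.conductive_length


def solute_rate_constant(params: TransportParams, probe: ProbeSystem, geom: RootGeometry) -> float:
    """Rate constant of solute permeation ksr = Ar·Psr/Vx, s⁻¹ (t½s = ln 2/ksr)."""
    vx = xylem_volume(geom)
    if vx <= 0:
        raise ValueError("xylem volume must be > 0; check geometry")
    return probe.Ar * params.Psr / vx


def _time_grid(duration: float, dt: float) -> np.ndarray:
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if duration < 10 * dt:
        raise ValueError("duration must cover at least 10 samples")
    n = int(round(duration / dt)) + 1
    return np.arange(n) * dt


def simulate_hydrostatic_relaxation(
    params: TransportParams,
    probe: ProbeSystem,
    P_ss: float,
    deltaP0: float,
    duration: float,
    dt: float,
) -> PressureTrace:
    """Noise-free hydrostatic relaxation P(t) = P_ss + ΔP₀·e^(−kwr·t).

    ``P_ss`` is the steady-state root pressure (MPa), ``deltaP0`` the imposed
    offset at t = 0 (positive for a push, negative for a pull).
    """
    kwr = hydrostatic_rate_constant(params, probe)
    t = _time_grid(duration, dt)
    p = P_ss + deltaP0 * np.exp(-kwr * t)
    return PressureTrace(
        t, p, "hydrostatic_step", deltaP0,
        meta={"kwr": kwr, "P_ss": P_ss, "t_half_w": LN2 / kwr},
    )


def _biphasic_offset(t: np.ndarray, kwr: float, ksr: float) -> np.ndarray:
    """Unit-amplitude biphasic kernel kwr/(kwr−ksr)·(e^(−ksr t) − e^(−kwr t))."""
    if math.isclose(kwr, ksr, rel_tol=1e-12, abs_tol=0.0):
        return kwr * t * np.exp(-kwr * t)
    return kwr / (kwr - ksr) * (np.exp(-ksr * t) - np.exp(-kwr * t))


def simulate_osmotic_response(
    params: TransportParams,
    probe: ProbeSystem,
    geom: RootGeometry,
    P0: float,
    delta_pi: float,
    duration: float,
    dt: float,
) -> PressureTrace:
    """Noise-free biphasic osmotic response to a medium step Δπ°s > 0.

    Exosmotic convention: raising the medium osmotic pressure depresses root
    pressure; the trace starts at P₀, dips to its minimum at tmin and (for a
    permeating solute, ksr > 0) recovers back to P₀.  For an impermeant solute
    (Psr = 0) it falls mono-exponentially to P₀ − σ·Δπ°s.
    """
    if delta_pi <= 0:
        raise ValueError("delta_pi must be > 0 (osmotic step up)")
    kwr = hydrostatic_rate_constant(params, probe)
    if kwr <= 0:
        raise ValueError("kwr must be > 0; check transport/probe configuration")
    ksr = solute_rate_constant(params, probe, geom)
    t = _time_grid(duration, dt)
    if ksr == 0.0:
        offset = 1.0 - np.exp(-kwr * t)
    else:
        offset = _biphasic_offset(t, kwr, ksr)
    p = P0 - params.sigma * delta_pi * offset
    return PressureTrace(
        t, p, "osmotic_step", delta_pi,
        meta={"kwr": kwr, "ksr": ksr, "P0": P0, "sigma": params.sigma},
    )


def analytic_tmin(kwr: float, ksr: float) -> float:
    """Time of the pressure minimum, tmin = ln(kwr/ksr)/(kwr−ksr), s.

    Requires kwr > ksr > 0 (water phase faster than solute phase); for an
    impermeant solute (ksr = 0) there is no finite minimum.
    """
    if ksr <= 0:
        raise ValueError("no finite minimum for ksr = 0 (impermeant solute)")
    if kwr <= ksr:
        raise ValueError(f"require kwr > ksr, got kwr={kwr}, ksr={ksr}")
    return math.log(kwr / ksr) / (kwr - ksr)


def analytic_delta_pr(sigma: float, delta_pi: float, kwr: float, ksr: float) -> float:
    """Analytic depth ΔPr of the biphasic minimum (positive, MPa).

    ΔPr = σ·Δπ·kwr/(kwr−ksr)·(e^(−ksr·tmin) − e^(−kwr·tmin)); satisfies the
    exact identity (ΔPr/Δπ)·e^(ksr·tmin) = σ.
    """
    tmin = analytic_tmin(kwr, ksr)
    return sigma * delta_pi * float(_biphasic_offset(np.asarray([tmin]), kwr, ksr)[0])
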