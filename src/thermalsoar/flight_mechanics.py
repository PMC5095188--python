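"""Banked-turn force balance and derived aerodynamic quantities.

A bird thermalling at constant airspeed v on a circle of radius r makes a
balanced turn: the lift acceleration l (lift force per unit mass) tilts by
the bank angle theta so that its vertical component supports weight and its
horizontal component supplies the centripetal acceleration,

    l * cos(theta) = g,          l * sin(theta) = v**2 / r,

whence l = sqrt(g**2 + (v**2 / r)**2) and theta = atan(v**2 / (g * r)).
With the wing loading m/S (kg m^-2) and air density rho the lift
coefficient follows from the lift equation L = 0.5 * rho * v**2 * S * C_L:

    C_L = 2 * l * (m/S) / (rho * v**2).

At constant C_L and wing loading, level flight in thinner air requires
airspeed scaled by sqrt(rho_low / rho_high); banking inflates the sink rate
relative to straight gliding by cos(theta)**(-3/2).

Air density comes from a per-fix input column when available, otherwise
from the International Standard Atmosphere (troposphere) as a function of
altitude, or from the ideal-gas law given pressure and temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

G = 9.81
"""Gravitational acceleration, m s^-2 (altitude variation ignored)."""

R_SPECIFIC_AIR = 287.058
"""Specific gas constant of dry air, J kg^-1 K^-1."""

DEFAULT_WING_LOADING = 10.54
"""Population-mean wing loading m/S of Himalayan vultures, kg m^-2
(measured on 26 individuals; individual mass varies too much with feeding
to use per-bird values)."""

# ISA troposphere constants
_ISA_T0 = 288.15  # K at sea level
_ISA_P0 = 101_325.0  # Pa at sea level
_ISA_LAPSE = 0.0065  # K/m
_ISA_EXP = 5.25588  # g / (R * lapse)
_ISA_TOP = 11_000.0  # m, tropopause


@dataclass(frozen=True)
class Morphometrics:
    """Bird mass and wing area; wing loading m/S drives the lift equation."""

    mass: float | None = None  # kg
    wing_area: float | None = None  # m^2
    wing_loading: float = DEFAULT_WING_LOADING  # kg m^-2

    def __post_init__(self) -> None:
        if self.mass is not None and self.wing_area is not None:
            if self.mass <= 0 or self.wing_area <= 0:
                raise DomainError("mass and wing area must be positive")
            object.__setattr__(self, "wing_loading", self.mass / self.wing_area)
        if self.wing_loading <= 0:
            raise DomainError("wing loading must be positive")


@dataclass
class LoopKinematics:
    """Per-segment derived flight quantities."""

    segment_id: str
    v: float  # airspeed, m/s
    omega: float  # angular rate, rad/s
    radius: float  # m
    bank: float  # radians
    lift_accel: float  # m s^-2
    lift_coeff: float
    rho: float  # kg m^-3
    rho_source: str  # "column" | "isa"
    altitude: float  # m a.m.s.l.
    vertical_speed: float  # m/s


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise DomainError(f"{name} must be positive, got {value}")


def circle_radius(v: float, omega: float) -> float:
    """Circling radius r = v / omega (m)."""
    _require_positive(v=v, omega=omega)
    return v / omega


def lift_acceleration(v: float, r: float) -> float:
    """Lift per unit mass in a balanced turn: sqrt(g^2 + (v^2/r)^2)."""
    _require_positive(v=v, r=r)
    return float(np.hypot(G, v * v / r))


def bank_angle(v: float, r: float) -> float:
    """Bank angle theta = atan(v^2 / (g r)), radians."""
    _require_positive(v=v, r=r)
    return float(np.arctan2(v * v / r, G))


def lift_coefficient(l: float, wing_loading: float, rho: float, v: float) -> float:
    """C_L = 2 l (m/S) / (rho v^2), dimensionless."""
    _require_positive(l=l, wing_loading=wing_loading, rho=rho, v=v)
    return 2.0 * l * wing_loading / (rho * v * v)


def airspeed_compensation(rho_low: float, rho_high: float) -> float:
    """Fractional airspeed increase needed between two air densities.

    At constant lift coefficient and wing loading, supporting the same
    weight in air thinned from ``rho_low`` to ``rho_high`` requires
    v_high / v_low = sqrt(rho_low / rho_high); the return value is that
    ratio minus one.
    """
    _require_positive(rho_low=rho_low, rho_high=rho_high)
    if rho_low < rho_high:
        raise DomainError("rho_low must be >= rho_high (inputs swapped?)")
    return float(np.sqrt(rho_low / rho_high) - 1.0)


def sink_rate_turn_correction(theta: float) -> tuple[float, float]:
    """Sink-rate penalty of banking at angle ``theta`` (radians).

    Returns ``(penalty_factor, best_improvement)``: the turning sink rate is
    the straight-glide sink rate times ``cos(theta)**(-3/2)``, and
    ``best_improvement = 1 - cos(theta)**(3/2)`` is the fractional sink-rate
    reduction attainable by rolling wings-level.
    """
    if not 0 <= theta < np.pi / 2:
        raise DomainError(f"bank angle must lie in [0, pi/2), got {theta}")
    c32 = np.cos(theta) ** 1.5
    return float(1.0 / c32), float(1.0 - c32)


def air_density(pressure: float, temperature: float) -> float:
    """Ideal-gas density rho = p / (R_air T), kg m^-3 (p in Pa, T in K)."""
    _require_positive(pressure=pressure, temperature=temperature)
    return pressure / (R_SPECIFIC_AIR * temperature)


def isa_density(altitude):
    """International Standard Atmosphere density at ``altitude`` (m).

    Valid in the troposphere, 0 <= altitude <= 11000 m; vectorised.
    """
    h = np.asarray(altitude, float)
    if np.any(h < 0) or np.any(h > _ISA_TOP):
        raise DomainError("ISA altitude must lie in [0, 11000] m")
    T = _ISA_T0 - _ISA_LAPSE * h
    p = _ISA_P0 * (T / _ISA_T0) ** _ISA_EXP
    rho = p / (R_SPECIFIC_AIR * T)
    return float(rho) if np.isscalar(altitude) else rho


def isa_altitude(rho: float) -> float:
    """Altitude (m) at which the ISA troposphere has density ``rho``."""
    from scipy.optimize import brentq

    _require_positive(rho=rho)
    lo, hi = isa_density(_ISA_TOP), isa_density(0.0)
    if not lo <= rho <= hi:
        raise DomainError(f"density {rho} outside ISA troposphere range")
    return float(brentq(lambda h: isa_density(h) - rho, 0.0, _ISA_TOP, xtol=1e-6))


def resolve_density(column_value: float, altitude: float,
                    allow_isa_fallback: bool = True) -> tuple[float, str] | None:
    """Pick the air density for a segment: input column first, ISA second.

    Returns ``(rho, source)`` or ``None`` when no source is available
    (segment is then dropped from the kinematics, mirroring the handling
    of track segments without reanalysis annotation).
    """
    if np.isfinite(column_value):
        return float(column_value), "column"
    if allow_isa_fallback and 0 <= altitude <= _ISA_TOP:
        return float(isa_density(altitude)), "isa"
    return None


def segment_kinematics(segment, wind, v: float,
                       wing_loading: float = DEFAULT_WING_LOADING,
                       allow_isa_fallback: bool = True) -> LoopKinematics | None:
    """Full banked-turn kinematics for one accepted loop segment.

    ``v`` is the wind-corrected airspeed; the angular rate comes from the
    segment's cumulative turn.  Returns ``None`` when no air-density source
    is available.
    """
    from .loop_segmentation import angular_rate

    omega = angular_rate(segment)
    dens = resolve_density(segment.air_density, segment.mean_altitude,
                           allow_isa_fallback)
    if dens is None:
        return None
    rho, source = dens
    r = circle_radius(v, omega)
    l = lift_acceleration(v, r)
    return LoopKinematics(
        segment_id=segment.segment_id,
        v=v,
        omega=omega,
        radius=r,
        bank=bank_angle(v, r),
        lift_accel=l,
        lift_coeff=lift_coefficient(l, wing_loading, rho, v),
        rho=rho,
        rho_source=source,
        altitude=segment.mean_altitude,
        vertical_speed=segment.vertical_speed,
    )
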