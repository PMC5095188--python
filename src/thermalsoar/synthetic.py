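"""Synthetic thermalling-flight generator with known ground truth.

Emulates the data the pipeline is built for: 10-min bursts of 1 Hz GPS
fixes from a bird circling in a thermal.  The kinematic model is the same
balanced turn the analysis assumes — a circle of constant radius flown at
constant airspeed, drifting with a constant horizontal wind, climbing at a
constant rate — plus white Gaussian GPS noise per horizontal coordinate:

    p(t) = w * t + r * (cos(s*w_rate*t + phi0), sin(s*w_rate*t + phi0)) + noise

with angular rate w_rate = v / r and turn direction s = +/-1.  The planar
path is inverse-projected to lon/lat about the start position and air
density is assigned per fix from the ISA troposphere (or a fixed value /
custom profile).  Every 30-s analysis window has its true wind, airspeed,
angular rate, radius, bank angle, lift acceleration and lift coefficient
recorded, so each pipeline stage can be checked against ground truth.

``simulate_population`` generates the altitude-gradient scenario: one
track per bird per altitude level, with the airspeed at each level set by
inverting the lift equation at constant lift coefficient,
v = sqrt(2 g (m/S) / (rho C_L)), and the radius scaled as v^2 so the bank
angle stays constant — the behavioural strategy of a soarer compensating
for thin air without changing wing configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .flight_mechanics import (
    G,
    bank_angle,
    isa_altitude,
    isa_density,
    lift_acceleration,
    lift_coefficient,
)
from .track_io import MOVEBANK_COLUMNS, Track, planar_to_geodetic

WINDOW_STEP = 30  # seconds per analysis window


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario for one simulated thermalling burst.

    Defaults mirror observed Himalayan-vulture thermalling: airspeeds
    around 8–16 m/s, radii of 20–60 m, ~1 m/s climb, metre-level GPS noise,
    densities following the standard atmosphere.  ``rng_seed`` is mandatory:
    there is no implicit randomness.
    """

    rng_seed: int
    airspeed: float = 11.0  # m/s
    radius: float = 30.0  # m
    turn_direction: int = 1  # +1 counterclockwise, -1 clockwise
    wind_east: float = 3.0  # m/s
    wind_north: float = -2.0  # m/s
    climb_rate: float = 1.0  # m/s
    start_altitude: float = 1000.0  # m a.m.s.l.
    burst_length: int = 600  # seconds of flight (burst has length+1 fixes)
    gps_noise_sigma: float = 0.5  # m per horizontal coordinate
    density_model: object = "isa"  # "isa" | float | callable(altitude)->rho
    wing_loading: float = 10.54  # kg m^-2, for the truth lift coefficient
    start_lon: float = 90.40  # deg (eastern Himalaya)
    start_lat: float = 27.50  # deg
    individual_id: str = "sim-bird"
    start_time: str = "2015-03-01T06:00:00"

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.airspeed <= 0:
            raise ConfigurationError("airspeed and radius must be positive")
        if self.turn_direction not in (+1, -1):
            raise ConfigurationError("turn_direction must be +1 or -1")
        if np.hypot(self.wind_east, self.wind_north) >= self.airspeed:
            raise ConfigurationError(
                "wind must be slower than airspeed for a conforming scenario"
            )
        if self.gps_noise_sigma < 0:
            raise ConfigurationError("gps_noise_sigma must be non-negative")


def _density_of(model, altitude):
    if callable(model):
        return model(altitude)
    if isinstance(model, (int, float)):
        return np.full_like(np.asarray(altitude, float), float(model))
    if model == "isa":
        return isa_density(altitude)
    raise ConfigurationError(f"unknown density model: {model!r}")


def simulate_thermalling_track(config: SimulationConfig
                               ) -> tuple[Track, pd.DataFrame]:
    """Simulate one burst; returns the track and per-window ground truth.

    The truth table has one row per non-overlapping 30-s window (windows
    share their boundary fix, as in the analysis), with every quantity the
    pipeline later estimates.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.burst_length + 1
    t = np.arange(n, dtype=float)
    omega = config.airspeed / config.radius
    s = config.turn_direction
    phi0 = float(rng.uniform(0.0, 2.0 * np.pi))

    x = config.wind_east * t + config.radius * (
        np.cos(s * omega * t + phi0) - np.cos(phi0))
    y = config.wind_north * t + config.radius * (
        np.sin(s * omega * t + phi0) - np.sin(phi0))
    if config.gps_noise_sigma > 0:
        x = x + rng.normal(0.0, config.gps_noise_sigma, n)
        y = y + rng.normal(0.0, config.gps_noise_sigma, n)
    altitude = config.start_altitude + config.climb_rate * t
    lon, lat = planar_to_geodetic(x, y, config.start_lon, config.start_lat)
    rho = np.asarray(_density_of(config.density_model, altitude), float)

    times = (np.datetime64(config.start_time, "s")
             + np.arange(n).astype("timedelta64[s]"))
    track = Track(
        individual_id=config.individual_id,
        times=times,
        lon=np.asarray(lon, float),
        lat=np.asarray(lat, float),
        altitude=altitude,
        air_density=rho,
    )

    rows = []
    for k in range(config.burst_length // WINDOW_STEP):
        start = k * WINDOW_STEP
        h_mid = config.start_altitude + config.climb_rate * (start + WINDOW_STEP / 2)
        rho_mid = float(np.asarray(_density_of(config.density_model, h_mid)))
        r, v = config.radius, config.airspeed
        l = lift_acceleration(v, r)
        rows.append(
            {
                "individual_id": config.individual_id,
                "window": k,
                "start_fix": start,
                "wind_east": config.wind_east,
                "wind_north": config.wind_north,
                "v": v,
                "omega": omega,
                "radius": r,
                "bank": bank_angle(v, r),
                "lift_accel": l,
                "lift_coeff": lift_coefficient(l, config.wing_loading, rho_mid, v),
                "rho": rho_mid,
                "altitude": h_mid,
                "vertical_speed": config.climb_rate,
                "turn_direction": s,
            }
        )
    return track, pd.DataFrame(rows)


@dataclass(frozen=True)
class PopulationConfig:
    """Altitude-gradient scenario: constant lift coefficient across levels.

    ``n_levels`` air densities are evenly spaced from ``rho_low`` (densest,
    lowest flight) to ``rho_high``; each bird flies one burst per level at
    the airspeed that keeps C_L = ``constant_cl``, with radius scaled as
    v^2 to hold the bank angle fixed.  The base altitude of each burst is
    chosen so the mid-climb altitude sits exactly at the level's density.
    """

    rng_seed: int
    n_birds: int = 4
    n_levels: int = 12
    rho_low: float = 1.099  # kg m^-3
    rho_high: float = 0.646
    constant_cl: float = 1.787
    wing_loading: float = 10.54
    radius_low: float = 28.3  # m at rho_low
    climb_rate: float = 1.0
    burst_length: int = 300
    gps_noise_sigma: float = 0.0
    max_wind: float = 3.0  # m/s, per-track wind magnitude drawn U(0, max)

    def __post_init__(self) -> None:
        if not 0.5 < self.constant_cl < 3:
            raise ConfigurationError("constant_cl must lie in (0.5, 3)")
        if self.rho_low <= self.rho_high:
            raise ConfigurationError("rho_low must exceed rho_high")


def level_airspeed(rho: float, constant_cl: float, wing_loading: float) -> float:
    """Airspeed keeping C_L constant at density rho (lift ~ weight, l = g)."""
    return float(np.sqrt(2.0 * G * wing_loading / (rho * constant_cl)))


def simulate_population(config: PopulationConfig
                        ) -> tuple[list[Track], pd.DataFrame]:
    """One track per bird per altitude level, plus the merged truth table."""
    rng = np.random.default_rng(config.rng_seed)
    rhos = np.linspace(config.rho_low, config.rho_high, config.n_levels)
    v_low = level_airspeed(config.rho_low, config.constant_cl, config.wing_loading)

    tracks: list[Track] = []
    truths: list[pd.DataFrame] = []
    for bird in range(config.n_birds):
        for k, rho in enumerate(rhos):
            v = level_airspeed(rho, config.constant_cl, config.wing_loading)
            radius = config.radius_low * (v / v_low) ** 2
            h_mid = isa_altitude(float(rho))
            wind_speed = float(rng.uniform(0.0, config.max_wind))
            wind_dir = float(rng.uniform(0.0, 2.0 * np.pi))
            sub = SimulationConfig(
                rng_seed=int(rng.integers(0, 2**31 - 1)),
                airspeed=v,
                radius=radius,
                turn_direction=1 if (bird + k) % 2 == 0 else -1,
                wind_east=wind_speed * np.cos(wind_dir),
                wind_north=wind_speed * np.sin(wind_dir),
                climb_rate=config.climb_rate,
                start_altitude=h_mid - config.climb_rate * config.burst_length / 2,
                burst_length=config.burst_length,
                gps_noise_sigma=config.gps_noise_sigma,
                wing_loading=config.wing_loading,
                individual_id=f"bird{bird:02d}-L{k:02d}",
                start_time=str(
                    np.datetime64("2015-03-01T06:00:00")
                    + np.timedelta64(bird * 24 + k, "h")
                ),
            )
            track, truth = simulate_thermalling_track(sub)
            truth.insert(1, "level", k)
            truth.insert(2, "bird", bird)
            tracks.append(track)
            truths.append(truth)
    return tracks, pd.concat(truths, ignore_index=True)


def write_movebank_csv(tracks: list[Track] | Track, path) -> None:
    """Write tracks in the Movebank-style schema the reader accepts."""
    if isinstance(tracks, Track):
        tracks = [tracks]
    frames = []
    for tr in tracks:
        frames.append(
            pd.DataFrame(
                {
                    MOVEBANK_COLUMNS["timestamp"]: np.datetime_as_string(tr.times),
                    MOVEBANK_COLUMNS["lon"]: tr.lon,
                    MOVEBANK_COLUMNS["lat"]: tr.lat,
                    MOVEBANK_COLUMNS["altitude"]: tr.altitude,
                    MOVEBANK_COLUMNS["individual_id"]: tr.individual_id,
                    MOVEBANK_COLUMNS["air_density"]: tr.air_density,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
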