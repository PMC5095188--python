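"""Shared fixture builders: analytic loop windows with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from thermalsoar.loop_segmentation import LoopSegment, heading_series
from thermalsoar.track_io import PlanarWindow, ground_velocity


def make_planar_loop(
    v_air: float = 11.0,
    radius: float = 30.0,
    wind: tuple[float, float] = (0.0, 0.0),
    turn_direction: int = 1,
    phi0: float = 0.7,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    n: int = 31,
) -> LoopSegment:
    """Build a LoopSegment directly in planar coordinates.

    The path is an exact drifting circle (plus optional Gaussian position
    noise), so the true wind, airspeed and angular rate are known without
    any geodetic round trip.  The full-turn criterion is NOT enforced:
    slow, wide circles can be built for estimator tests.
    """
    t = np.arange(float(n))
    omega = v_air / radius
    s = turn_direction
    x = wind[0] * t + radius * np.cos(s * omega * t + phi0)
    y = wind[1] * t + radius * np.sin(s * omega * t + phi0)
    if noise_sigma > 0:
        if rng is None:
            raise ValueError("noise requires an rng")
        x = x + rng.normal(0.0, noise_sigma, n)
        y = y + rng.normal(0.0, noise_sigma, n)
    window = PlanarWindow(
        ref_lon=0.0,
        ref_lat=0.0,
        x=x - x.mean(),
        y=y - y.mean(),
        z=np.full(n, 1000.0),
        t=t,
    )
    vel = ground_velocity(window)
    headings = heading_series(vel)
    turn = float(headings[-1] - headings[0]) if headings is not None else 0.0
    return LoopSegment(
        segment_id="fixture",
        individual_id="fixture-bird",
        window=window,
        velocities=vel,
        cumulative_turn=turn if turn != 0.0 else 2.0 * np.pi * s,
        turn_direction=s,
        start_time=np.datetime64("2015-03-01T06:00:00"),
        mean_altitude=1000.0,
        air_density=np.nan,
        vertical_speed=0.0,
    )


@pytest.fixture
def planar_loop():
    return make_planar_loop
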