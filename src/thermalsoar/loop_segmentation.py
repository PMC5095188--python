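"""Detection of full-circle thermalling windows and the angular rate.

A window is 31 consecutive 1 Hz fixes (30 s).  It qualifies as a loop
segment when the unwrapped heading of the ground velocity accumulates at
least one full turn (|cumulative turn| >= 2*pi) and the ground speed never
drops below a minimal gate.  Accepted windows tile the burst: consecutive
30-s intervals share their boundary fix, so segments never overlap in time.

The mean angular rate of a segment is omega = |cumulative turn| / 30 s;
with the mean airspeed v it yields the circling radius r = v / omega.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .track_io import (
    PlanarWindow,
    Track,
    WINDOW_FIXES,
    WINDOW_SECONDS,
    ground_velocity,
    project_window,
)

logger = logging.getLogger(__name__)

MIN_SPEED = 0.5
"""Minimum ground speed (m/s) for a defined heading; far below soaring speeds."""

FULL_TURN = 2.0 * np.pi


@dataclass
class LoopSegment:
    """A 30-s window in which the bird completed at least one full circle."""

    segment_id: str
    individual_id: str
    window: PlanarWindow
    velocities: np.ndarray  # (31, 2) east/north m/s
    cumulative_turn: float  # signed radians across the 31 fixes
    turn_direction: int  # +1 counterclockwise, -1 clockwise
    start_time: np.datetime64
    mean_altitude: float
    air_density: float  # kg m^-3, nan when missing
    vertical_speed: float  # m/s over the window
    duration: float = WINDOW_SECONDS


def heading_series(velocities: np.ndarray) -> np.ndarray | None:
    """Unwrapped heading (radians, atan2(north, east)) of a velocity series.

    Returns ``None`` (reject-window signal) when any speed is at or below
    the :data:`MIN_SPEED` gate, where the heading is ill-defined.
    """
    v = np.asarray(velocities, float)
    speeds = np.hypot(v[:, 0], v[:, 1])
    if np.any(speeds <= MIN_SPEED):
        return None
    return np.unwrap(np.arctan2(v[:, 1], v[:, 0]))


def find_loop_segments(track: Track, stats: dict | None = None) -> list[LoopSegment]:
    """Greedy left-to-right scan for non-overlapping full-circle windows.

    Within each burst the earliest qualifying 31-fix window is accepted and
    the scan resumes at its last fix (30-s intervals tile continuously);
    otherwise the start advances by one fix.  Windows never cross burst
    boundaries.  The result is deterministic and in time order.

    ``stats``, when given, receives the counters ``windows_scanned`` and
    ``windows_accepted``.
    """
    segments: list[LoopSegment] = []
    scanned = 0
    for b, (lo, hi) in enumerate(track.bursts):
        i = lo
        while i + WINDOW_FIXES <= hi:
            scanned += 1
            sl = slice(i, i + WINDOW_FIXES)
            window = project_window(
                track.times[sl], track.lon[sl], track.lat[sl], track.altitude[sl]
            )
            vel = ground_velocity(window)
            headings = heading_series(vel)
            turn = None if headings is None else headings[-1] - headings[0]
            if turn is not None and abs(turn) >= FULL_TURN:
                rho = track.air_density[sl]
                rho_val = float(np.nanmean(rho)) if np.any(np.isfinite(rho)) else np.nan
                segments.append(
                    LoopSegment(
                        segment_id=f"{track.individual_id}-b{b}-f{i - lo}",
                        individual_id=track.individual_id,
                        window=window,
                        velocities=vel,
                        cumulative_turn=float(turn),
                        turn_direction=1 if turn > 0 else -1,
                        start_time=track.times[i],
                        mean_altitude=float(np.mean(window.z)),
                        air_density=rho_val,
                        vertical_speed=float(window.z[-1] - window.z[0])
                        / WINDOW_SECONDS,
                    )
                )
                i += WINDOW_FIXES - 1  # next interval starts at this window's last fix
            else:
                i += 1
    if stats is not None:
        stats["windows_scanned"] = scanned
        stats["windows_accepted"] = len(segments)
    logger.debug(
        "track %s: %d windows scanned, %d loop segments",
        track.individual_id, scanned, len(segments),
    )
    return segments


def angular_rate(segment: LoopSegment) -> float:
    """Mean angular rate omega = |cumulative turn| / 30 s (rad/s)."""
    return abs(segment.cumulative_turn) / segment.duration


def segments_table(segments: list[LoopSegment]):
    """Summary table: one row per accepted segment."""
    import pandas as pd

    return pd.DataFrame(
        {
            "segment_id": [s.segment_id for s in segments],
            "individual_id": [s.individual_id for s in segments],
            "start_time": [s.start_time for s in segments],
            "mean_altitude": [s.mean_altitude for s in segments],
            "cumulative_turn_deg": [np.rad2deg(s.cumulative_turn) for s in segments],
            "omega_rad_s": [angular_rate(s) for s in segments],
        }
    )
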