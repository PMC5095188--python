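"""Reading, validation and local planar projection of 1 Hz GPS tracks.

Tracks arrive as Movebank-style CSV exports: one row per GPS fix with a UTC
timestamp, geographic coordinates in decimal degrees, height above mean sea
level in metres and an individual identifier.  Loggers record bursts of
1 Hz fixes (typically 10 min); any gap larger than one second splits a burst.

All downstream geometry happens in a local tangent plane.  Because a single
thermalling loop spans at most a few hundred metres, an equirectangular
projection centred on each 30-s window is accurate to well below GPS noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInputError, SegmentationContractError

logger = logging.getLogger(__name__)

R_EARTH = 6_371_000.0
"""Mean Earth radius in metres used by the equirectangular projection."""

#: Default column names of a Movebank CSV export, mapped to internal names.
MOVEBANK_COLUMNS: dict[str, str] = {
    "timestamp": "timestamp",
    "lon": "location-long",
    "lat": "location-lat",
    "altitude": "height-above-msl",
    "individual_id": "individual-local-identifier",
    "air_density": "air-density",
}

#: Window contract: 31 consecutive fixes spanning exactly 30 seconds.
WINDOW_FIXES = 31
WINDOW_SECONDS = 30.0


@dataclass(frozen=True)
class GPSFix:
    """A single georeferenced 1 Hz sample.

    ``air_density`` (kg m^-3) is optional; ``nan`` marks a missing value.
    """

    timestamp: np.datetime64
    lon: float
    lat: float
    altitude: float
    individual_id: str
    air_density: float = float("nan")


@dataclass
class Track:
    """Ordered 1 Hz fixes of one individual, partitioned into bursts.

    Arrays are aligned; ``bursts`` holds half-open ``(start, stop)`` index
    ranges within which timestamps increase in exact 1-s steps.
    """

    individual_id: str
    times: np.ndarray  # datetime64[s]
    lon: np.ndarray
    lat: np.ndarray
    altitude: np.ndarray
    air_density: np.ndarray  # nan where missing
    bursts: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("lon", "lat", "altitude", "air_density"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"array '{name}' misaligned with times")
        if not self.bursts:
            self.bursts = split_bursts(self.times)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    def fix(self, i: int) -> GPSFix:
        return GPSFix(
            timestamp=self.times[i],
            lon=float(self.lon[i]),
            lat=float(self.lat[i]),
            altitude=float(self.altitude[i]),
            individual_id=self.individual_id,
            air_density=float(self.air_density[i]),
        )


@dataclass
class PlanarWindow:
    """A 31-fix window in local tangent-plane coordinates.

    ``x`` is metres east and ``y`` metres north of the window centroid;
    ``z`` is altitude (m a.m.s.l.); ``t`` is seconds from the first fix.
    """

    ref_lon: float
    ref_lat: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    t: np.ndarray


def split_bursts(times: np.ndarray) -> list[tuple[int, int]]:
    """Partition a sorted datetime64[s] array into bursts of exact 1-s sampling.

    A burst breaks wherever the step differs from one second (gaps longer
    than 1 s by definition; sub-second steps cannot occur after truncation
    to whole seconds and duplicate removal).
    """
    n = len(times)
    if n == 0:
        return []
    dt = np.diff(times).astype("timedelta64[s]").astype(int)
    breaks = np.flatnonzero(dt != 1) + 1
    edges = np.concatenate(([0], breaks, [n]))
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def _clean_frame(df: pd.DataFrame, column_map: dict[str, str]) -> pd.DataFrame:
    required = ("timestamp", "lon", "lat", "altitude", "individual_id")
    missing = [column_map[k] for k in required if column_map[k] not in df.columns]
    if missing:
        raise ConfigurationError(f"required column(s) not found: {missing}")

    out = pd.DataFrame(
        {
            "timestamp": pd.to_datetime(
                df[column_map["timestamp"]], utc=True, errors="coerce"
            ),
            "lon": pd.to_numeric(df[column_map["lon"]], errors="coerce"),
            "lat": pd.to_numeric(df[column_map["lat"]], errors="coerce"),
            "altitude": pd.to_numeric(df[column_map["altitude"]], errors="coerce"),
            "individual_id": df[column_map["individual_id"]].astype(str),
        }
    )
    dens_col = column_map.get("air_density")
    if dens_col is not None and dens_col in df.columns:
        out["air_density"] = pd.to_numeric(df[dens_col], errors="coerce")
    else:
        out["air_density"] = np.nan

    n_raw = len(out)
    valid = (
        out["timestamp"].notna()
        & out["lon"].between(-180, 180, inclusive="right")
        & out["lat"].between(-90, 90)
        & out["altitude"].between(-500, 12_000)
    )
    dropped = int(n_raw - valid.sum())
    if dropped:
        logger.info("dropped %d of %d rows with unparseable/out-of-range fields",
                    dropped, n_raw)
    out = out[valid]
    # density outside its physical band is treated as missing, not fatal
    bad_rho = out["air_density"].notna() & ~out["air_density"].between(0.1, 1.6)
    if bad_rho.any():
        logger.info("masked %d implausible air-density values", int(bad_rho.sum()))
        out.loc[bad_rho, "air_density"] = np.nan
    return out


def _frame_to_track(g: pd.DataFrame, individual_id: str) -> Track:
    # truncate to whole seconds, stable-sort by time, keep first duplicate
    times = g["timestamp"].dt.tz_localize(None).values.astype("datetime64[s]")
    order = np.argsort(times, kind="stable")
    times = times[order]
    keep = np.concatenate(([True], np.diff(times).astype(int) != 0))
    n_dup = int((~keep).sum())
    if n_dup:
        logger.info("individual %s: dropped %d duplicate timestamps",
                    individual_id, n_dup)
    idx = order[keep]
    track = Track(
        individual_id=individual_id,
        times=times[keep],
        lon=g["lon"].values[idx].astype(float),
        lat=g["lat"].values[idx].astype(float),
        altitude=g["altitude"].values[idx].astype(float),
        air_density=g["air_density"].values[idx].astype(float),
    )
    logger.info("individual %s: %d fixes in %d bursts",
                individual_id, len(track), track.n_bursts)
    return track


def read_tracks(path, column_map: dict[str, str] | None = None) -> list[Track]:
    """Read a Movebank-style CSV and return one :class:`Track` per individual.

    ``column_map`` maps the internal names (``timestamp``, ``lon``, ``lat``,
    ``altitude``, ``individual_id``, ``air_density``) to the CSV headers;
    unspecified entries fall back to the Movebank export defaults.
    Rows with unparseable timestamps or out-of-range coordinates are dropped
    and counted in the log.
    """
    cmap = dict(MOVEBANK_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path)
    clean = _clean_frame(df, cmap)
    if clean.empty:
        raise EmptyInputError(f"no valid GPS rows in {path}")
    return [
        _frame_to_track(g, str(ind))
        for ind, g in clean.groupby("individual_id", sort=True)
    ]


def read_track(path, column_map: dict[str, str] | None = None) -> Track:
    """Read a CSV known to contain a single individual."""
    tracks = read_tracks(path, column_map)
    if len(tracks) != 1:
        raise ConfigurationError(
            f"{path} contains {len(tracks)} individuals; use read_tracks()"
        )
    return tracks[0]


def geodetic_to_planar(lon, lat, ref_lon: float, ref_lat: float):
    """Equirectangular projection about (ref_lon, ref_lat): metres east/north."""
    x = R_EARTH * np.cos(np.deg2rad(ref_lat)) * np.deg2rad(np.asarray(lon) - ref_lon)
    y = R_EARTH * np.deg2rad(np.asarray(lat) - ref_lat)
    return x, y


def planar_to_geodetic(x, y, ref_lon: float, ref_lat: float):
    """Inverse of :func:`geodetic_to_planar`."""
    lon = ref_lon + np.rad2deg(np.asarray(x) / (R_EARTH * np.cos(np.deg2rad(ref_lat))))
    lat = ref_lat + np.rad2deg(np.asarray(y) / R_EARTH)
    return lon, lat


def project_window(times, lon, lat, altitude) -> PlanarWindow:
    """Project 31 consecutive fixes spanning exactly 30 s about their centroid.

    The centroid of the fixes maps to (0, 0); ``t`` holds seconds from the
    first fix.  Raises :class:`SegmentationContractError` if the window does
    not satisfy the 31-fix / 30-s contract.
    """
    times = np.asarray(times, dtype="datetime64[s]")
    if len(times) != WINDOW_FIXES:
        raise SegmentationContractError(
            f"expected {WINDOW_FIXES} fixes, got {len(times)}"
        )
    span = (times[-1] - times[0]).astype(int)
    if span != WINDOW_SECONDS:
        raise SegmentationContractError(f"window spans {span} s, expected 30 s")
    ref_lon = float(np.mean(lon))
    ref_lat = float(np.mean(lat))
    x, y = geodetic_to_planar(lon, lat, ref_lon, ref_lat)
    t = (times - times[0]).astype(int).astype(float)
    return PlanarWindow(
        ref_lon=ref_lon,
        ref_lat=ref_lat,
        x=np.asarray(x, float),
        y=np.asarray(y, float),
        z=np.asarray(altitude, float),
        t=t,
    )


def ground_velocity(window: PlanarWindow) -> np.ndarray:
    """Per-fix horizontal ground velocity (m/s east, north), shape (31, 2).

    Central differences at interior fixes, second-order one-sided (3-point)
    differences at the two ends.  Second-order endpoints keep the phase bias
    of the heading series below 0.6% of a full turn for loop periods >= 10 s;
    first-order endpoints would bias the cumulative turn by a factor 29/30.
    """
    p = np.column_stack([window.x, window.y])
    v = np.empty_like(p)
    v[1:-1] = (p[2:] - p[:-2]) / 2.0
    v[0] = (-3.0 * p[0] + 4.0 * p[1] - p[2]) / 2.0
    v[-1] = (3.0 * p[-1] - 4.0 * p[-2] + p[-3]) / 2.0
    return v
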