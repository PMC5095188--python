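"""End-to-end orchestration: tracks -> segments -> wind -> kinematics -> stats.

The stage order is fixed: loop segmentation, per-loop wind fit, airspeed,
banked-turn kinematics with air-density annotation, then the altitude
statistics.  Every filter (non-converged wind fits, wind-dominant loops,
segments without a density source) is counted so the final sample size is
auditable from the run report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import altitude_analysis as aa
from . import flight_mechanics as fm
from .loop_segmentation import LoopSegment, find_loop_segments, segments_table
from .track_io import Track, read_tracks
from .wind_airspeed import QUALITY_OK, airspeed, fit_loop_wind, wind_support_check

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one analysis run; defaults match the study settings."""

    input_path: Path | str | None = None
    out_dir: Path | str = "thermalsoar-out"
    column_map: dict | None = None
    wing_loading: float = fm.DEFAULT_WING_LOADING  # kg m^-2
    allow_isa_fallback: bool = True  # ISA density when no input column
    k_bins: int = 15
    tail_fraction: float = 0.05
    bin_quantities: tuple = ("lift_coeff", "lift_accel", "vertical_speed",
                            "v", "radius")
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        from .errors import ConfigurationError

        with open(path) as fh:
            try:
                raw = yaml.safe_load(fh) or {}
            except yaml.YAMLError as exc:
                raise ConfigurationError(f"invalid YAML in {path}: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunReport:
    """Counts at every filter stage plus the paths written."""

    n_tracks: int = 0
    n_fixes: int = 0
    n_bursts: int = 0
    windows_scanned: int = 0
    segments_accepted: int = 0
    wind_converged: int = 0
    wind_not_converged: int = 0
    wind_dominant: int = 0
    density_annotated: int = 0
    density_missing: int = 0
    outputs: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_tracks": self.n_tracks,
            "n_fixes": self.n_fixes,
            "n_bursts": self.n_bursts,
            "windows_scanned": self.windows_scanned,
            "segments_accepted": self.segments_accepted,
            "wind_converged": self.wind_converged,
            "wind_not_converged": self.wind_not_converged,
            "wind_dominant": self.wind_dominant,
            "density_annotated": self.density_annotated,
            "density_missing": self.density_missing,
            "outputs": {k: str(v) for k, v in self.outputs.items()},
            "stage_seconds": self.stage_seconds,
        }


def analyze_tracks(
    tracks: list[Track], config: RunConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, RunReport]:
    """Run the in-memory pipeline; returns (segments, wind, kinematics, report).

    The kinematics table has one row per segment that survived every
    filter: full circle, converged wind fit, wind slower than airspeed,
    air density available.
    """
    config = config or RunConfig()
    report = RunReport(n_tracks=len(tracks))

    t0 = time.perf_counter()
    all_segments: list[LoopSegment] = []
    for track in tracks:
        report.n_fixes += len(track)
        report.n_bursts += track.n_bursts
        stats: dict = {}
        all_segments.extend(find_loop_segments(track, stats=stats))
        report.windows_scanned += stats["windows_scanned"]
    report.segments_accepted = len(all_segments)
    seg_df = segments_table(all_segments)
    report.stage_seconds["segmentation"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    wind_rows = []
    kin_rows = []
    for seg in all_segments:
        est = fit_loop_wind(seg)
        if not est.converged:
            report.wind_not_converged += 1
            continue
        report.wind_converged += 1
        v = airspeed(seg, est)
        flag = wind_support_check(seg, est, v)
        wind_rows.append(
            {
                "segment_id": seg.segment_id,
                "wind_east": est.wind_east,
                "wind_north": est.wind_north,
                "wind_speed": est.wind_speed,
                "wind_direction_deg": est.wind_direction_deg,
                "airspeed": v,
                "rms_residual": est.rms_residual,
                "quality_flag": flag,
            }
        )
        if flag != QUALITY_OK:
            report.wind_dominant += 1
            continue
        kin = fm.segment_kinematics(
            seg, est, v,
            wing_loading=config.wing_loading,
            allow_isa_fallback=config.allow_isa_fallback,
        )
        if kin is None:
            report.density_missing += 1
            continue
        report.density_annotated += 1
        kin_rows.append(vars(kin).copy())
    report.stage_seconds["wind_kinematics"] = round(time.perf_counter() - t0, 3)

    wind_df = pd.DataFrame(wind_rows)
    kin_df = pd.DataFrame(kin_rows)
    return seg_df, wind_df, kin_df, report


def run_pipeline(config: RunConfig) -> RunReport:
    """File-to-file run: read CSV, analyze, write all output tables.

    Writes segments.csv, wind.csv, kinematics.csv and, when enough
    segments survive, bins_<quantity>.csv, groups.json and model.json.
    An empty result (no accepted segments) is not an error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("thermalsoar")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    try:
        tracks = read_tracks(config.input_path, config.column_map)
        seg_df, wind_df, kin_df, report = analyze_tracks(tracks, config)

        seg_df.to_csv(out / "segments.csv", index=False)
        wind_df.to_csv(out / "wind.csv", index=False)
        kin_df.to_csv(out / "kinematics.csv", index=False)
        report.outputs = {
            "segments": out / "segments.csv",
            "wind": out / "wind.csv",
            "kinematics": out / "kinematics.csv",
        }

        n = len(kin_df)
        if n >= max(config.k_bins, int(2 / config.tail_fraction)):
            for q in config.bin_quantities:
                bins = aa.bin_summaries(kin_df, q, k=config.k_bins)
                bins.to_csv(out / f"bins_{q}.csv", index=False)
                report.outputs[f"bins_{q}"] = out / f"bins_{q}.csv"
            low, high = aa.density_tail_groups(kin_df, config.tail_fraction)
            comparison = aa.compare_groups(low, high)
            (out / "groups.json").write_text(
                json.dumps(comparison.to_dict(), indent=2))
            report.outputs["groups"] = out / "groups.json"
            model = aa.fit_speed_density_model(kin_df)
            result = {"speed_density": model.to_dict()}
            if np.ptp(kin_df["altitude"].values) >= 1000:
                trend, trend_fit = aa.radius_altitude_trend(kin_df)
                result["radius_trend_pct_per_km"] = trend
                result["radius_trend_fit"] = trend_fit.to_dict()
            (out / "model.json").write_text(json.dumps(result, indent=2))
            report.outputs["model"] = out / "model.json"
        else:
            logger.info("only %d kinematic segments; skipping group statistics", n)

        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
        logger.info("run complete: %s", report.to_dict())
        return report
    finally:
        root.removeHandler(handler)
        handler.close()
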