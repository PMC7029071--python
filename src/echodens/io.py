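"""Data model, delimited-text readers, and configuration.

All downstream stages consume the objects produced here; no stage re-parses
raw files.  Record collections (calls, weather, sites, sun table) are
pandas DataFrames with standardized, validated columns; per-species and
per-detector parameters are frozen dataclasses.

Conventions: angles are degrees at I/O and radians internally; distances
meters; densities per m^2 internally, reported per km^2 (x 1e6).
Timestamps are naive local times with a fixed UTC offset given in config.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import warnings
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import solar

__all__ = [
    "SpeciesProfile",
    "DetectorProfile",
    "Config",
    "SchemaError",
    "read_calls",
    "read_weather",
    "read_sites",
    "read_sun",
    "write_calls",
    "assign_nights",
    "assign_periods",
    "validate_calls",
    "compute_nights",
    "load_config",
]

VARIANTS = ("strict", "generous")


class SchemaError(ValueError):
    """A mandatory column is missing or a file-level invariant is violated."""


@dataclasses.dataclass(frozen=True)
class SpeciesProfile:
    """Acoustic and movement parameters of one species.

    Parameters
    ----------
    main_frequency : float
        Main call frequency in kHz; drives atmospheric absorption.
    spl_min, spl_max : float
        Source sound pressure level range (dB SPL at ``reference_distance``
        of the detector profile).  The full range characterizes the
        uncertainty in the detection radius.
    signal_angles : tuple of float
        Candidate acoustic signal (call cone) angles alpha, degrees.
    flight_speed_v : float
        Average flight speed, m/s (the v of the encounter model).
    home_range_area : float
        Median minimum-convex-polygon home range, km^2; converts mean
        abundance lambda into density.
    flight_altitude_dh : float
        Mean flight height above the microphone, meters (0 = calls at
        microphone level; >0 engages the altitude-corrected profile width).
    """

    name: str
    main_frequency: float
    spl_min: float
    spl_max: float
    signal_angles: tuple[float, ...]
    flight_speed_v: float
    home_range_area: float
    flight_altitude_dh: float = 0.0

    def __post_init__(self) -> None:
        if self.spl_min > self.spl_max:
            raise ValueError(f"{self.name}: spl_min {self.spl_min} > spl_max {self.spl_max}")
        for a in self.signal_angles:
            if not 0.0 < a <= 360.0:
                raise ValueError(f"{self.name}: signal angle {a} outside (0, 360]")
        if self.flight_speed_v <= 0:
            raise ValueError(f"{self.name}: flight_speed_v must be positive")
        if self.home_range_area <= 0:
            raise ValueError(f"{self.name}: home_range_area must be positive")
        if self.flight_altitude_dh < 0:
            raise ValueError(f"{self.name}: flight_altitude_dh must be >= 0")


@dataclasses.dataclass(frozen=True)
class DetectorProfile:
    """Recorder geometry and sensitivity.

    ``sensor_angle_theta`` is the detection angle theta in degrees
    (default 200).  ``threshold_spl`` is the faintest level (dB SPL at the
    microphone) still triggering a recording; it is a calibration constant
    of the device chain, not a physical constant.
    """

    sensor_angle_theta: float = 200.0
    mic_height: float = 2.20
    threshold_spl: float = 20.0
    reference_distance: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.sensor_angle_theta <= 360.0:
            raise ValueError("sensor_angle_theta must be in (0, 360]")
        if self.reference_distance <= 0:
            raise ValueError("reference_distance must be positive")


@dataclasses.dataclass
class Config:
    """Validated pipeline configuration (species, detector, settings)."""

    species: dict[str, SpeciesProfile]
    detector: DetectorProfile
    periods: list[dict[str, Any]]
    settings: dict[str, Any]
    literature_densities: dict[str, float]
    utc_offset_hours: float = 0.0
    solar_mode: str = "table"  # "table" or "noaa"
    latitude: float | None = None
    longitude: float | None = None


# ---------------------------------------------------------------------------
# readers


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: Any) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


def _report_bad_rows(df: pd.DataFrame, bad: pd.Series, what: str, path: Any, on_bad: str):
    """Drop rows flagged bad, recording 1-based data line numbers in attrs."""
    errors = [(int(i) + 2, what) for i in df.index[bad]]  # +2: header + 1-based
    if errors:
        msg = f"{path}: {len(errors)} row(s) dropped ({what}); first at line {errors[0][0]}"
        if on_bad == "raise":
            raise SchemaError(msg)
        warnings.warn(msg)
    out = df[~bad].copy()
    out.attrs["row_errors"] = list(df.attrs.get("row_errors", [])) + errors
    return out


def read_calls(path, schema: Mapping[str, str] | None = None, on_bad: str = "warn") -> pd.DataFrame:
    """Read identified call-pass records from a delimited text file.

    Expected columns: site_id, species, timestamp (ISO 8601), variant
    ("strict" | "generous"), excluded (boolean outlier flag).  ``schema``
    optionally maps expected names to actual file column names.  Malformed
    rows are dropped and reported (line numbers in ``df.attrs['row_errors']``);
    excluded records are retained but flagged.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    _require_columns(df, ["site_id", "species", "timestamp", "variant", "excluded"], path)
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad_ts = ts.isna()
    df = df.assign(timestamp=ts)
    df = _report_bad_rows(df, bad_ts, "unparseable timestamp", path, on_bad)
    bad_var = ~df["variant"].isin(VARIANTS)
    df = _report_bad_rows(df, bad_var, "unknown identification variant", path, on_bad)
    df["excluded"] = df["excluded"].astype(bool)
    df["site_id"] = df["site_id"].astype(str)
    df = df.sort_values(["site_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    return df


def write_calls(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if len(out):
        out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_weather(path, on_bad: str = "warn") -> pd.DataFrame:
    """Read per-site weather logs: site_id, timestamp, temperature_c, rh_pct."""
    df = pd.read_csv(path)
    _require_columns(df, ["site_id", "timestamp", "temperature_c", "rh_pct"], path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    df["site_id"] = df["site_id"].astype(str)
    bad = (df["rh_pct"] < 0) | (df["rh_pct"] > 100) | df["rh_pct"].isna()
    return _report_bad_rows(df, bad, "relative humidity outside [0, 100]", path, on_bad)


def read_sites(path) -> pd.DataFrame:
    """Read site metadata: site_id, elevation_m, device_id plus covariates."""
    df = pd.read_csv(path)
    _require_columns(df, ["site_id", "elevation_m", "device_id"], path)
    df["site_id"] = df["site_id"].astype(str)
    if not np.isfinite(df["elevation_m"]).all():
        raise SchemaError(f"{path}: non-finite elevation")
    if df["site_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicated site_id")
    return df


def read_sun(path) -> pd.DataFrame:
    """Read the sun table: date, sunset, sunrise (one row per night)."""
    df = pd.read_csv(path)
    _require_columns(df, ["date", "sunset", "sunrise"], path)
    df["date"] = pd.to_datetime(df["date"]).dt.normalize()
    df["sunset"] = pd.to_datetime(df["sunset"], format="ISO8601")
    df["sunrise"] = pd.to_datetime(df["sunrise"], format="ISO8601")
    if (df["sunrise"] <= df["sunset"]).any():
        raise SchemaError(f"{path}: sunrise must be after sunset")
    return df


# ---------------------------------------------------------------------------
# night / period bookkeeping


def assign_nights(calls: pd.DataFrame) -> pd.DataFrame:
    """Attach ``night_id``: the date at sunset of the night a call belongs to.

    Calls after midnight are assigned to the previous calendar date (the
    evening's date); recordings run from sunset to sunrise, so shifting by
    12 h before taking the date is exact at temperate latitudes.
    """
    out = calls.copy()
    ts = pd.to_datetime(out["timestamp"])  # tolerate empty/object frames
    out["night_id"] = (ts - pd.Timedelta(hours=12)).dt.normalize()
    return out


def assign_periods(calls: pd.DataFrame, periods: Sequence[Mapping[str, Any]]) -> pd.DataFrame:
    """Attach ``period_id`` from user-defined sampling periods.

    ``periods`` is a list of mappings with keys id, start, end (dates,
    inclusive, compared against night_id).  Nights outside every period get
    period_id NA.
    """
    out = calls if "night_id" in calls.columns else assign_nights(calls)
    out = out.copy()
    pid = pd.Series(pd.NA, index=out.index, dtype="object")
    for p in periods:
        start = pd.Timestamp(p["start"])
        end = pd.Timestamp(p["end"])
        mask = (out["night_id"] >= start) & (out["night_id"] <= end)
        pid[mask] = p["id"]
    out["period_id"] = pid
    return out


def compute_nights(calls: pd.DataFrame, sun: pd.DataFrame) -> pd.DataFrame:
    """One SurveyNight row per (site, night) present in ``calls``.

    Columns: site_id, night_id, sunset, sunrise, duration_t (seconds,
    sunset to sunrise).  Every night_id must appear in the sun table.
    """
    if "night_id" not in calls.columns:
        calls = assign_nights(calls)
    pairs = calls[["site_id", "night_id"]].drop_duplicates()
    merged = pairs.merge(sun, left_on="night_id", right_on="date", how="left")
    missing = merged["sunset"].isna()
    if missing.any():
        dates = sorted(str(d) for d in merged.loc[missing, "night_id"].dt.date.unique())
        raise SchemaError(f"sun table missing night(s): {', '.join(dates)}")
    merged["duration_t"] = (merged["sunrise"] - merged["sunset"]).dt.total_seconds()
    if (merged["duration_t"] <= 0).any():
        raise SchemaError("non-positive night duration")
    return merged[["site_id", "night_id", "sunset", "sunrise", "duration_t"]].reset_index(drop=True)


def validate_calls(calls: pd.DataFrame, nights: pd.DataFrame, on_bad: str = "warn") -> pd.DataFrame:
    """Reject calls falling outside their night's [sunset, sunrise] window."""
    merged = calls.merge(nights[["site_id", "night_id", "sunset", "sunrise"]],
                         on=["site_id", "night_id"], how="left")
    bad = (merged["timestamp"] < merged["sunset"]) | (merged["timestamp"] > merged["sunrise"])
    bad |= merged["sunset"].isna()
    out = _report_bad_rows(merged, bad.to_numpy(), "timestamp outside its night", "calls", on_bad)
    return out.drop(columns=["sunset", "sunrise"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# configuration


def load_config(path) -> Config:
    """Load and validate the YAML pipeline configuration.

    Defaults are filled for unspecified fields (theta 200 deg, mic height
    2.20 m, threshold 20 dB SPL, reference distance 0.1 m, flight altitude
    0 m); every type invariant is checked at load time with a named error.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}

    det_raw = raw.get("detector", {})
    detector = DetectorProfile(
        sensor_angle_theta=float(det_raw.get("sensor_angle_theta_deg", 200.0)),
        mic_height=float(det_raw.get("mic_height_m", 2.20)),
        threshold_spl=float(det_raw.get("threshold_spl_db", 20.0)),
        reference_distance=float(det_raw.get("reference_distance_m", 0.1)),
    )

    species: dict[str, SpeciesProfile] = {}
    for name, sp in (raw.get("species") or {}).items():
        species[name] = SpeciesProfile(
            name=name,
            main_frequency=float(sp["main_frequency_khz"]),
            spl_min=float(sp["spl_min_db"]),
            spl_max=float(sp["spl_max_db"]),
            signal_angles=tuple(float(a) for a in sp.get("signal_angles_deg", (25.0, 42.0, 70.0))),
            flight_speed_v=float(sp["flight_speed_m_s"]),
            home_range_area=float(sp.get("home_range_area_km2", 1.0)),
            flight_altitude_dh=float(sp.get("flight_altitude_dh_m", 0.0)),
        )
        if detector.threshold_spl >= species[name].spl_min:
            raise ValueError(
                f"detector threshold {detector.threshold_spl} dB must lie below "
                f"{name}'s minimum source SPL {species[name].spl_min} dB"
            )

    sol = raw.get("solar", {})
    return Config(
        species=species,
        detector=detector,
        periods=list(raw.get("periods", [])),
        settings=dict(raw.get("settings", {})),
        literature_densities={k: float(v) for k, v in (raw.get("literature_densities") or {}).items()},
        utc_offset_hours=float(raw.get("timezone_offset_hours", 0.0)),
        solar_mode=sol.get("mode", "table"),
        latitude=sol.get("latitude"),
        longitude=sol.get("longitude"),
    )


def sun_table_for(config: Config, dates: Sequence[dt.date]) -> pd.DataFrame:
    """Build a sun table from the configured solar approximation."""
    if config.solar_mode != "noaa":
        raise ValueError("sun_table_for requires solar mode 'noaa' (else supply sun.csv)")
    if config.latitude is None or config.longitude is None:
        raise ValueError("solar mode 'noaa' needs latitude and longitude in config")
    return solar.build_sun_table(list(dates), config.latitude, config.longitude,
                                 config.utc_offset_hours)
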