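"""Acoustic detection radius from source level and atmospheric conditions.

The level reaching the microphone from a source at distance r is

    L(r) = SPL_source - 20 log10(r / d0) - a * r

with spherical spreading from the reference distance d0 and a the
atmospheric absorption coefficient (dB/m) of ISO 9613-1 (classical +
rotational losses plus the O2 and N2 vibrational relaxation terms).  The
detection radius is the unique r with L(r) equal to the detector
threshold; L is strictly decreasing in r, so a bracketed root finder
converges to machine accuracy.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import DetectorProfile, SpeciesProfile

__all__ = [
    "AtmosphericConditions",
    "RangeResult",
    "barometric_pressure",
    "absorption_coefficient",
    "detection_distance",
    "range_envelope",
    "night_conditions",
    "ranges_for_nights",
    "calibrate_threshold",
]

P_REF = 101_325.0  # Pa, sea-level standard pressure
T_REF = 293.15  # K, ISO 9613-1 reference temperature (20 C)
T_TRIPLE = 273.16  # K, triple point of water


@dataclasses.dataclass(frozen=True)
class AtmosphericConditions:
    """Ambient temperature (C), relative humidity (%) and pressure (Pa)."""

    temperature: float
    relative_humidity: float
    pressure: float = P_REF

    def __post_init__(self) -> None:
        if self.pressure <= 0:
            raise ValueError("pressure must be positive")
        if not -40.0 <= self.temperature <= 50.0:
            raise ValueError(f"temperature {self.temperature} C outside [-40, 50]")
        if not 0.0 <= self.relative_humidity <= 100.0:
            raise ValueError("relative humidity outside [0, 100]")


@dataclasses.dataclass(frozen=True)
class RangeResult:
    """Detection radius for one (species, SPL, conditions) combination."""

    species: str
    spl: float
    conditions: AtmosphericConditions
    r: float
    absorption: float


def barometric_pressure(elevation: float) -> float:
    """Standard-atmosphere pressure (Pa) at an elevation (m above sea level).

    International Standard Atmosphere troposphere model:
    p = p0 (1 - L h / T0)^(g M / (R L)).
    """
    if not -500.0 <= elevation <= 9000.0:
        raise ValueError(f"elevation {elevation} m outside [-500, 9000]")
    return P_REF * (1.0 - 2.25577e-5 * elevation) ** 5.25588


def absorption_coefficient(frequency: float, conditions: AtmosphericConditions) -> float:
    """ISO 9613-1 pure-tone atmospheric absorption, dB per meter.

    Parameters
    ----------
    frequency : float
        Tone frequency in kHz (valid 10-200 kHz for this pipeline).
    conditions : AtmosphericConditions
        Ambient temperature, relative humidity, pressure.
    """
    if not 10.0 <= frequency <= 200.0:
        raise ValueError(f"frequency {frequency} kHz outside [10, 200]")
    f = frequency * 1e3  # Hz
    t_k = conditions.temperature + 273.15
    p_rel = conditions.pressure / P_REF
    t_rel = t_k / T_REF

    # molar concentration of water vapour (%), from saturation pressure
    p_sat_rel = 10.0 ** (-6.8346 * (T_TRIPLE / t_k) ** 1.261 + 4.6151)
    h = conditions.relative_humidity * p_sat_rel / p_rel

    # relaxation frequencies of O2 and N2 (Hz)
    fr_o = p_rel * (24.0 + 4.04e4 * h * (0.02 + h) / (0.391 + h))
    fr_n = p_rel / np.sqrt(t_rel) * (9.0 + 280.0 * h * np.exp(-4.170 * (t_rel ** (-1.0 / 3.0) - 1.0)))

    alpha = 8.686 * f**2 * (
        1.84e-11 / p_rel * np.sqrt(t_rel)
        + t_rel ** (-2.5)
        * (
            0.01275 * np.exp(-2239.1 / t_k) / (fr_o + f**2 / fr_o)
            + 0.1068 * np.exp(-3352.0 / t_k) / (fr_n + f**2 / fr_n)
        )
    )
    return float(alpha)


def _received_level(r: float, spl_source: float, a: float, d0: float) -> float:
    return spl_source - 20.0 * np.log10(r / d0) - a * r


def detection_distance(
    spl_source: float,
    detector: DetectorProfile,
    frequency: float,
    conditions: AtmosphericConditions,
    species: str = "",
) -> RangeResult:
    """Detection radius: root of the spherical-spreading + absorption loss.

    Raises ``ValueError`` when the source level does not exceed the detector
    threshold at the reference distance (no positive range exists).
    """
    d0 = detector.reference_distance
    thr = detector.threshold_spl
    if spl_source <= thr:
        raise ValueError(
            f"source level {spl_source} dB does not exceed threshold {thr} dB"
        )
    a = absorption_coefficient(frequency, conditions)

    def f(r: float) -> float:
        return _received_level(r, spl_source, a, d0) - thr

    # zero-absorption bound: spreading alone brings the level to threshold
    r_hi = d0 * 10.0 ** ((spl_source - thr) / 20.0)
    if f(r_hi) > 0:  # numerically flat a; treat bound as the root
        r_root = r_hi
    else:
        r_root = brentq(f, d0, r_hi, xtol=1e-10, rtol=8.9e-16)
    return RangeResult(species=species, spl=spl_source, conditions=conditions,
                       r=float(r_root), absorption=a)


def _spl_grid(spl_min: float, spl_max: float, step: float) -> np.ndarray:
    n = int(round((spl_max - spl_min) / step)) if spl_max > spl_min else 0
    grid = spl_min + step * np.arange(n + 1)
    grid = grid[grid <= spl_max + 1e-9]
    if grid.size == 0 or grid[-1] < spl_max - 1e-9:
        grid = np.append(grid, spl_max)
    return grid


def range_envelope(
    profile: SpeciesProfile,
    detector: DetectorProfile,
    conditions: Iterable[AtmosphericConditions],
    spl_step: float = 10.0,
) -> tuple[float, float, list[RangeResult]]:
    """(r_min, r_max) over the SPL x conditions grid, plus every RangeResult.

    The source-SPL grid runs from the species' spl_min to spl_max in
    ``spl_step`` dB steps (endpoints always included), characterizing the
    uncertainty from unknown per-call source levels.
    """
    conditions = list(conditions)
    if not conditions:
        raise ValueError("need at least one atmospheric condition")
    results = [
        detection_distance(spl, detector, profile.main_frequency, cond, species=profile.name)
        for spl in _spl_grid(profile.spl_min, profile.spl_max, spl_step)
        for cond in conditions
    ]
    rs = [res.r for res in results]
    return min(rs), max(rs), results


def night_conditions(
    nights: pd.DataFrame, weather: pd.DataFrame, sites: pd.DataFrame
) -> pd.DataFrame:
    """Per (site, night) atmospheric conditions for the range computation.

    Temperature and humidity are within-night medians of the site's weather
    series (median for robustness to logger spikes); pressure comes from
    site elevation through the standard atmosphere.  Nights with no weather
    records get NA conditions.
    """
    w = weather.copy()
    w["night_id"] = (w["timestamp"] - pd.Timedelta(hours=12)).dt.normalize()
    med = (
        w.groupby(["site_id", "night_id"])[["temperature_c", "rh_pct"]]
        .median()
        .reset_index()
    )
    out = nights.merge(med, on=["site_id", "night_id"], how="left")
    out = out.merge(sites[["site_id", "elevation_m"]], on="site_id", how="left")
    out["pressure_pa"] = out["elevation_m"].map(barometric_pressure)
    return out


def ranges_for_nights(
    profile: SpeciesProfile,
    detector: DetectorProfile,
    conds: pd.DataFrame,
    spl_step: float = 10.0,
) -> pd.DataFrame:
    """Detection radius per (site, night, SPL grid point).

    ``conds`` is the output of :func:`night_conditions`.  Nights lacking
    weather are dropped with a count in ``attrs['n_missing_conditions']``.
    """
    ok = conds.dropna(subset=["temperature_c", "rh_pct", "pressure_pa"])
    rows = []
    for _, row in ok.iterrows():
        cond = AtmosphericConditions(row["temperature_c"], row["rh_pct"], row["pressure_pa"])
        for spl in _spl_grid(profile.spl_min, profile.spl_max, spl_step):
            res = detection_distance(spl, detector, profile.main_frequency, cond,
                                     species=profile.name)
            rows.append({
                "species": profile.name, "site_id": row["site_id"],
                "night_id": row["night_id"], "spl_db": spl,
                "temperature_c": cond.temperature, "rh_pct": cond.relative_humidity,
                "pressure_pa": cond.pressure,
                "absorption_db_per_m": res.absorption, "r_m": res.r,
            })
    out = pd.DataFrame(rows)
    out.attrs["n_missing_conditions"] = int(len(conds) - len(ok))
    return out


def calibrate_threshold(
    profiles: Sequence[SpeciesProfile],
    target_spans: Sequence[tuple[float, float]],
    conditions: Iterable[AtmosphericConditions],
    detector: DetectorProfile | None = None,
    spl_step: float = 10.0,
    bounds: tuple[float, float] = (0.0, 60.0),
) -> float:
    """Detector threshold (dB SPL) best matching target detection-range spans.

    The absolute sensitivity of the recorder chain is rarely known; given
    literature or previously published (r_min, r_max) spans per species,
    this finds the single threshold minimizing the summed squared log-ratio
    error of both span endpoints.  Golden-section search on a smooth
    1-D objective.
    """
    from scipy.optimize import minimize_scalar

    conditions = list(conditions)
    base = detector or DetectorProfile()

    def loss(thr: float) -> float:
        det = dataclasses.replace(base, threshold_spl=thr)
        total = 0.0
        for prof, (lo, hi) in zip(profiles, target_spans):
            r_min, r_max, _ = range_envelope(prof, det, conditions, spl_step)
            total += np.log(r_min / lo) ** 2 + np.log(r_max / hi) ** 2
        return total

    res = minimize_scalar(loss, bounds=bounds, method="bounded",
                          options={"xatol": 1e-3})
    return float(res.x)
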