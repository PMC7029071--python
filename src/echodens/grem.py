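"""Generalized random encounter model (gREM) density estimation.

A stationary acoustic sensor with detection angle theta records an animal
that calls within a cone of signal angle alpha whenever the sensor lies
inside the cone and the animal inside the sensor's sector of radius r.
Averaging the resulting one-dimensional encounter cross-section over
approach directions gives the mean profile width

    p_bar = (r / pi) * (theta * sin(alpha/2) - cos(alpha/2) + 1)

valid in the wide-sensor / narrow-signal regime (theta > pi, alpha < pi).
Density follows from the ideal-gas encounter rate:

    D = z / (v * t * p_bar)

with z the number of recorded passes, v the flight speed and t the total
recording time.  When animals fly a height dh above the microphone the
sphere-plane intersection shrinks the horizontal radius, giving the
altitude-corrected width p_bar = 2 * sqrt(r^2 - dh^2) * sin(alpha/2).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .io import DetectorProfile, SpeciesProfile

__all__ = [
    "DetectionGeometry",
    "UnsupportedRegimeError",
    "mean_profile_width",
    "profile_width_altitude",
    "grem_density",
    "estimate_grid",
    "summarize_grem",
]

M2_PER_KM2 = 1e6


class UnsupportedRegimeError(ValueError):
    """Geometry outside the regime the implemented profile formula covers."""


@dataclasses.dataclass(frozen=True)
class DetectionGeometry:
    """Encounter geometry: radius r (m), sensor angle theta and signal angle
    alpha (radians), and height offset dh (m) of the flight plane above the
    microphone."""

    r: float
    theta: float
    alpha: float
    dh: float = 0.0

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("r must be positive")
        if not 0.0 < self.theta <= 2.0 * np.pi:
            raise ValueError("theta must be in (0, 2*pi]")
        if not 0.0 < self.alpha <= 2.0 * np.pi:
            raise ValueError("alpha must be in (0, 2*pi]")
        if not 0.0 <= self.dh <= self.r:
            raise ValueError("dh must be in [0, r]")


def mean_profile_width(geometry: DetectionGeometry) -> float:
    """Mean profile width p_bar (m) for a wide sensor and a narrow call cone.

    Requires theta > pi and alpha < pi (the regime of the closed form
    above); other sensor/signal regimes need different sub-model formulas
    and are rejected rather than silently extrapolated.
    """
    if not (geometry.theta > np.pi and geometry.alpha < np.pi):
        raise UnsupportedRegimeError(
            f"mean_profile_width covers theta > pi and alpha < pi only "
            f"(got theta={geometry.theta:.4f}, alpha={geometry.alpha:.4f} rad)"
        )
    a2 = geometry.alpha / 2.0
    return geometry.r / np.pi * (geometry.theta * np.sin(a2) - np.cos(a2) + 1.0)


def profile_width_altitude(geometry: DetectionGeometry) -> float:
    """Altitude-corrected profile width 2*sqrt(r^2 - dh^2)*sin(alpha/2) (m).

    The flight plane a height dh above the microphone intersects the
    detection sphere in a disk of radius sqrt(r^2 - dh^2); at dh = r the
    disk degenerates to a point and the width is zero.
    """
    if geometry.dh > geometry.r:
        raise ValueError("dh > r: animal flies above the detection sphere")
    disk = np.sqrt(max(geometry.r**2 - geometry.dh**2, 0.0))
    return 2.0 * disk * np.sin(geometry.alpha / 2.0)


def grem_density(z: int, v: float, t: float, p_bar: float) -> float:
    """Density D = z / (v * t * p_bar), individuals per km^2.

    z is a pass count (>= 0), v m/s, t seconds, p_bar meters; the per-m^2
    rate is scaled by 1e6.
    """
    if z < 0 or int(z) != z:
        raise ValueError("z must be a non-negative integer")
    if v <= 0 or t <= 0 or p_bar <= 0:
        raise ValueError("v, t and p_bar must all be positive")
    return z / (v * t * p_bar) * M2_PER_KM2


def _profile_width(r: float, theta_rad: float, alpha_rad: float, dh: float) -> float:
    geom = DetectionGeometry(r=r, theta=theta_rad, alpha=alpha_rad, dh=min(dh, r))
    if dh > 0:
        return profile_width_altitude(geom)
    return mean_profile_width(geom)


def estimate_grid(
    calls: pd.DataFrame,
    nights: pd.DataFrame,
    profile: SpeciesProfile,
    detector: DetectorProfile,
    ranges: pd.DataFrame,
) -> pd.DataFrame:
    """One gREM density per (period, variant, alpha, SPL) grid cell.

    ``calls`` must already carry night_id and period_id and be restricted
    to one species; excluded (outlier-flagged) records are dropped here.
    z pools passes over all sites of a period; t sums the surveyed
    site-night durations; each SPL grid point uses the median over that
    period's per-night detection radii (from ``ranges``, the output of
    :func:`echodens.attenuation.ranges_for_nights`).

    Returns a tidy frame: species, period_id, variant, alpha_deg, spl_db,
    r_m, p_bar_m, z, t_s, density_per_km2.
    """
    calls = calls[~calls["excluded"]]
    theta = np.deg2rad(detector.sensor_angle_theta)
    night_period = _night_periods(calls, nights)
    rows = []
    for period, nd in night_period.groupby("period_id"):
        night_keys = nd[["site_id", "night_id"]].drop_duplicates()
        per_nights = nights.merge(night_keys, on=["site_id", "night_id"])
        if per_nights.empty:
            warnings.warn(f"period {period}: no surveyed nights, skipped")
            continue
        t_total = float(per_nights["duration_t"].sum())
        per_ranges = ranges.merge(night_keys, on=["site_id", "night_id"])
        r_by_spl = per_ranges.groupby("spl_db")["r_m"].median()
        pcalls = calls.merge(night_keys, on=["site_id", "night_id"])
        variants = sorted(calls["variant"].unique()) or ["strict", "generous"]
        for variant in variants:
            z = int((pcalls["variant"] == variant).sum())
            for alpha_deg in profile.signal_angles:
                alpha = np.deg2rad(alpha_deg)
                for spl, r in r_by_spl.items():
                    p_bar = _profile_width(r, theta, alpha, profile.flight_altitude_dh)
                    rows.append({
                        "species": profile.name, "period_id": period,
                        "variant": variant, "alpha_deg": alpha_deg,
                        "spl_db": float(spl), "r_m": float(r),
                        "p_bar_m": p_bar, "z": z, "t_s": t_total,
                        "density_per_km2": grem_density(z, profile.flight_speed_v,
                                                        t_total, p_bar),
                    })
    return pd.DataFrame(rows)


def _night_periods(calls: pd.DataFrame, nights: pd.DataFrame) -> pd.DataFrame:
    """Surveyed (site, night) -> period map.

    Survey effort is defined by the nights table (a surveyed night with
    zero passes still contributes recording time); when it lacks period
    labels they are taken from the calls.
    """
    if "period_id" in nights.columns:
        out = nights.dropna(subset=["period_id"])[["site_id", "night_id", "period_id"]]
        return out.drop_duplicates()
    if "period_id" not in calls.columns:
        raise ValueError("need a period_id column on nights or calls (see assign_periods)")
    out = calls.dropna(subset=["period_id"])[["site_id", "night_id", "period_id"]]
    return out.drop_duplicates()


def summarize_grem(grid: pd.DataFrame) -> pd.DataFrame:
    """Average estimated density per species x variant.

    The reported figure is the unweighted mean over sampling periods and
    over the alpha x SPL parameter grid (the pooling convention is isolated
    here so it can be switched without touching the estimator).
    """
    return (
        grid.groupby(["species", "variant"])["density_per_km2"]
        .mean()
        .rename("mean_density_per_km2")
        .reset_index()
    )
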