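"""Session-binned detection/nondetection histories for abundance modeling.

Each survey night is split into S within-night sessions on normalized time
(fraction of the night elapsed since sunset), with S chosen by Scott's
histogram bin-width rule on the pooled normalized call times.  Every
(night, session) pair is one sampling occasion; a site scores 1 on an
occasion if at least one pass fell in that session, 0 if the site was
surveyed that night without a pass, and missing if the site-night was not
surveyed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SessionGrid",
    "DetectionHistory",
    "normalize_time",
    "scott_session_count",
    "assign_sessions",
    "build_history",
]

MAX_SESSIONS = 48  # ~10-minute sessions on an 8 h night; bounds model size


@dataclasses.dataclass(frozen=True)
class SessionGrid:
    """S equal-width session bins on normalized night time [0, 1]."""

    n_sessions: int
    boundaries: tuple[float, ...]

    def __post_init__(self) -> None:
        b = self.boundaries
        if self.n_sessions < 1 or len(b) != self.n_sessions + 1:
            raise ValueError("boundaries must have n_sessions + 1 entries")
        if b[0] != 0.0 or b[-1] != 1.0 or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must rise strictly from 0 to 1")


@dataclasses.dataclass
class DetectionHistory:
    """Sites x occasions binary detection matrix with covariates.

    ``y`` holds 0/1 with NaN for unsurveyed site-nights.  Occasions are
    (night_id, slot) pairs, slot in 1..S.  Occasion covariates are
    site x occasion arrays (median within-session temperature and
    humidity, mean-imputed where missing with companion indicator
    arrays); site covariates are centered on their means.
    """

    sites: list[str]
    occasions: list[tuple[pd.Timestamp, int]]
    y: np.ndarray
    slot_index: np.ndarray  # per occasion, 1..S
    n_sessions: int
    occ_cov: dict[str, np.ndarray]
    site_cov: pd.DataFrame
    device: np.ndarray  # per site device label

    def __post_init__(self) -> None:
        vals = self.y[~np.isnan(self.y)]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("y entries must be 0, 1 or missing")
        if self.y.shape != (len(self.sites), len(self.occasions)):
            raise ValueError("y dimensions inconsistent with labels")


def normalize_time(timestamp: pd.Timestamp, sunset: pd.Timestamp, sunrise: pd.Timestamp) -> float:
    """Fraction of the night elapsed at ``timestamp`` (0 at sunset, 1 at sunrise)."""
    total = (sunrise - sunset).total_seconds()
    x = (pd.Timestamp(timestamp) - sunset).total_seconds() / total
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"timestamp {timestamp} outside its night")
    return x


def scott_session_count(times: Sequence[float]) -> SessionGrid:
    """Number of within-night sessions from Scott's histogram rule.

    Bin width h = 3.49 * sd * n^(-1/3) on the pooled normalized times;
    S = ceil(1/h), clamped to [1, 48].  Degenerate inputs (fewer than two
    distinct values) fall back to a single session.
    """
    x = np.asarray(list(times), dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        return SessionGrid(1, (0.0, 1.0))
    sd = float(np.std(x, ddof=1))
    h = 3.49 * sd * x.size ** (-1.0 / 3.0)
    s = int(np.clip(np.ceil(1.0 / h), 1, MAX_SESSIONS))
    return SessionGrid(s, tuple(np.linspace(0.0, 1.0, s + 1)))


def assign_sessions(times: Sequence[float], grid: SessionGrid) -> np.ndarray:
    """Slot (1..S) per normalized time; half-open [b_k, b_{k+1}) bins, the
    final bin closed at 1."""
    b = np.asarray(grid.boundaries)
    idx = np.searchsorted(b, np.asarray(times, dtype=float), side="right") - 1
    return np.clip(idx, 0, grid.n_sessions - 1) + 1


def build_history(
    calls: pd.DataFrame,
    nights: pd.DataFrame,
    grid: SessionGrid,
    sites: pd.DataFrame,
    weather: pd.DataFrame,
) -> DetectionHistory:
    """Detection/nondetection history for one species, variant and period.

    ``calls`` must be restricted to a single species/variant/period and
    carry night_id; ``nights`` lists every surveyed (site, night) with
    sunset/sunrise.  Occasions span every night in ``nights`` crossed with
    the session grid.  Deterministic: identical inputs give identical
    matrices.
    """
    site_ids = sorted(sites["site_id"].astype(str))
    night_ids = sorted(nights["night_id"].unique())
    s = grid.n_sessions
    occasions = [(pd.Timestamp(n), k) for n in night_ids for k in range(1, s + 1)]
    occ_index = {occ: j for j, occ in enumerate(occasions)}
    n_i, n_j = len(site_ids), len(occasions)
    site_pos = {sid: i for i, sid in enumerate(site_ids)}

    y = np.full((n_i, n_j), np.nan)
    surveyed = nights.set_index(["site_id", "night_id"])[["sunset", "sunrise"]]
    for (sid, nid), row in surveyed.iterrows():
        if sid in site_pos:
            for k in range(1, s + 1):
                y[site_pos[sid], occ_index[(pd.Timestamp(nid), k)]] = 0.0

    for _, c in calls.iterrows():
        key = (c["site_id"], c["night_id"])
        if key not in surveyed.index or c["site_id"] not in site_pos:
            continue
        sunset, sunrise = surveyed.loc[key, "sunset"], surveyed.loc[key, "sunrise"]
        x = normalize_time(c["timestamp"], sunset, sunrise)
        slot = int(assign_sessions([x], grid)[0])
        y[site_pos[c["site_id"]], occ_index[(pd.Timestamp(c["night_id"]), slot)]] = 1.0

    temp, hum = _session_weather(weather, surveyed, grid, site_pos, occ_index, (n_i, n_j))
    occ_cov = {}
    for name, arr in (("temp", temp), ("hum", hum)):
        missing = np.isnan(arr) & ~np.isnan(y)  # only surveyed cells matter
        filled = arr.copy()
        mean = np.nanmean(arr) if np.isfinite(arr).any() else 0.0
        filled[np.isnan(filled)] = mean
        occ_cov[name] = filled
        occ_cov[f"{name}_missing"] = missing.astype(float)

    site_df = sites.set_index(sites["site_id"].astype(str)).loc[site_ids]
    device = site_df["device_id"].to_numpy()
    cov_cols = [c for c in site_df.columns if c not in ("site_id", "device_id")]
    site_cov = site_df[cov_cols].copy()
    num = site_cov.select_dtypes(include=[np.number]).columns
    site_cov[num] = site_cov[num] - site_cov[num].mean()

    return DetectionHistory(
        sites=site_ids,
        occasions=occasions,
        y=y,
        slot_index=np.array([k for _, k in occasions]),
        n_sessions=s,
        occ_cov=occ_cov,
        site_cov=site_cov,
        device=device,
    )


def _session_weather(weather, surveyed, grid, site_pos, occ_index, shape):
    temp = np.full(shape, np.nan)
    hum = np.full(shape, np.nan)
    if weather is None or weather.empty:
        return temp, hum
    w = weather.copy()
    w["night_id"] = (w["timestamp"] - pd.Timedelta(hours=12)).dt.normalize()
    for (sid, nid), grp in w.groupby(["site_id", "night_id"]):
        key = (sid, nid)
        if key not in surveyed.index or sid not in site_pos:
            continue
        sunset, sunrise = surveyed.loc[key, "sunset"], surveyed.loc[key, "sunrise"]
        total = (sunrise - sunset).total_seconds()
        x = (grp["timestamp"] - sunset).dt.total_seconds() / total
        inside = (x >= 0) & (x <= 1)
        if not inside.any():
            continue
        slots = assign_sessions(x[inside].to_numpy(), grid)
        sub = grp[inside].assign(slot=slots)
        med = sub.groupby("slot")[["temperature_c", "rh_pct"]].median()
        for slot, row in med.iterrows():
            j = occ_index[(pd.Timestamp(nid), int(slot))]
            temp[site_pos[sid], j] = row["temperature_c"]
            hum[site_pos[sid], j] = row["rh_pct"]
    return temp, hum
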