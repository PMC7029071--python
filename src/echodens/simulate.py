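"""Synthetic-data generators providing ground truth for every stage.

Three generators:

* :func:`simulate_gas` -- the ideal-gas movement model: animals placed
  uniformly on a torus with uniform headings move ballistically (optional
  slow turning); a stationary sector detector at the center logs an
  encounter each time an animal *enters* the detectable state (within
  radius r, inside the sensor sector theta, and with the detector inside
  the animal's heading-centered call cone alpha).  This is the independent
  oracle for the encounter-model profile width and density formula.
* :func:`simulate_rn` -- the generative direction of the Royle-Nichols
  model: latent Poisson abundances, link-function covariate effects,
  Bernoulli detection histories.
* :func:`simulate_survey` -- an end-to-end survey faker writing the
  calls/weather/sites/sun file set the readers consume.

The movement simulation is two-dimensional; flight a fixed height above
the microphone is modeled by shrinking the detection radius to the
sphere-plane intersection disk (:func:`simulate_altitude`).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .grem import DetectionGeometry
from .histories import DetectionHistory
from .io import SpeciesProfile

__all__ = [
    "GasSimConfig",
    "GasSimResult",
    "RnSimTruth",
    "simulate_gas",
    "simulate_altitude",
    "simulate_rn",
    "simulate_survey",
]


@dataclasses.dataclass(frozen=True)
class GasSimConfig:
    """Ideal-gas simulation settings.

    ``true_density`` is in individuals per km^2; the arena is a square
    torus of side ``arena_side`` meters (at least 10 detection radii so
    wrap effects stay away from the detector); ``step_dt`` must resolve
    the detection region (at most r / (4 v) seconds).
    """

    true_density: float
    v: float
    geometry: DetectionGeometry
    duration: float
    arena_side: float | None = None
    step_dt: float | None = None
    turn_rate: float = 0.0
    seed: int = 0

    def resolved(self) -> "GasSimConfig":
        side = self.arena_side if self.arena_side is not None else 10.0 * self.geometry.r
        dt_ = self.step_dt if self.step_dt is not None else self.geometry.r / (8.0 * self.v)
        return dataclasses.replace(self, arena_side=side, step_dt=dt_)

    def validate(self) -> None:
        if self.true_density < 0:
            raise ValueError("true_density must be >= 0")
        if self.v <= 0 or self.duration <= 0:
            raise ValueError("v and duration must be positive")
        if self.arena_side is None or self.step_dt is None:
            raise ValueError("call resolved() first")
        if self.arena_side < 10.0 * self.geometry.r:
            raise ValueError("arena_side must be >= 10 * r")
        if self.step_dt > self.geometry.r / (4.0 * self.v):
            raise ValueError("step_dt must be <= r / (4 v)")


@dataclasses.dataclass
class GasSimResult:
    """Encounter log of one simulation: count z, per-event (time, entry
    position, heading), and the realized animal number."""

    z: int
    events: list[tuple[float, tuple[float, float], float]]
    realized_n: int
    seed: int


@dataclasses.dataclass
class RnSimTruth:
    """Ground truth behind a simulated detection history."""

    lambda_site: np.ndarray
    n_site: np.ndarray
    r_occasion: np.ndarray
    history: DetectionHistory
    seed: int


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


_FULL = 2.0 * np.pi - 1e-12


def _detectable_intervals(theta: float, alpha: float, phi: float):
    """Angular interval(s) of positions that are simultaneously inside the
    sensor sector and whose call cone (heading ``phi``) covers the detector.

    Returns None for the full disk, else a list of (a, b) intervals
    (b > a, width <= 2 pi), possibly empty.
    """
    if theta >= _FULL and alpha >= _FULL:
        return None
    if theta >= _FULL:
        c = phi + np.pi
        return [(c - alpha / 2.0, c + alpha / 2.0)]
    if alpha >= _FULL:
        return [(-theta / 2.0, theta / 2.0)]
    a1, b1 = -theta / 2.0, theta / 2.0
    a2, b2 = phi + np.pi - alpha / 2.0, phi + np.pi + alpha / 2.0
    a2 = _wrap_angle(np.array(a2)).item()
    b2 = a2 + alpha
    out = []
    for k in (-2.0 * np.pi, 0.0, 2.0 * np.pi):
        lo, hi = max(a1, a2 + k), min(b1, b2 + k)
        if hi > lo:
            out.append((lo, hi))
    return out


def _entry_intervals(x0, u, s_max, r, centers, pieces):
    """Per region copy, the path-length interval [s_in, s_out] spent inside.

    ``pieces`` is a list of (a, b) sub-sectors each of width <= pi (so each
    is a convex disk-and-two-half-planes region), or [None] for the full
    disk.  Convex pieces of one connected region are merged afterwards.
    Returns merged (s_in, s_out) pairs clipped to [0, s_max].
    """
    d0 = centers - x0[None, :]  # detector-copy centers relative to start
    proj = d0 @ u
    c_coef = (d0**2).sum(axis=1) - r * r
    disc = proj**2 - c_coef
    ok = disc > 0
    sq = np.sqrt(np.where(ok, disc, 0.0))
    lo_c, hi_c = proj - sq, proj + sq

    merged: list[list[tuple[float, float]]] = [[] for _ in range(len(centers))]
    for piece in pieces:
        lo = lo_c.copy()
        hi = hi_c.copy()
        valid = ok.copy()
        if piece is not None:
            a, b = piece
            # sector of width <= pi == two half-planes through the center:
            # cross(e_a, x - c) >= 0 and cross(x - c, e_b) >= 0
            for ex, ey, sign in ((np.cos(a), np.sin(a), 1.0),
                                 (np.cos(b), np.sin(b), -1.0)):
                # sign * (ex*(y(s)) - ey*(x(s))) >= 0, linear in s
                a0 = sign * (ex * (-d0[:, 1]) - ey * (-d0[:, 0]))
                a1 = sign * (ex * u[1] - ey * u[0])
                with np.errstate(divide="ignore", invalid="ignore"):
                    s_star = -a0 / a1
                inc = a1 > 0
                dec = a1 < 0
                lo = np.where(inc, np.maximum(lo, s_star), lo)
                hi = np.where(dec, np.minimum(hi, s_star), hi)
                valid &= ~((a1 == 0) & (a0 < 0))
        valid &= hi > lo
        valid &= (hi > 0) & (lo < s_max)
        for i in np.nonzero(valid)[0]:
            merged[i].append((max(lo[i], 0.0), min(hi[i], s_max)))

    out = []
    for i, ivals in enumerate(merged):
        if not ivals:
            continue
        ivals.sort()
        cur_lo, cur_hi = ivals[0]
        comps = []
        for lo_i, hi_i in ivals[1:]:
            if lo_i <= cur_hi + 1e-9:
                cur_hi = max(cur_hi, hi_i)
            else:
                comps.append((cur_lo, cur_hi))
                cur_lo, cur_hi = lo_i, hi_i
        comps.append((cur_lo, cur_hi))
        for s_in, s_out in comps:
            out.append((i, s_in, s_out))
    return out


def _candidate_centers(x0, u, s_max, r, side):
    """Lattice translates of the detector whose region the path can touch."""
    step = side / 2.0
    s_grid = np.arange(0.0, s_max + step, step)
    pts = x0[None, :] + s_grid[:, None] * u[None, :]
    cells = np.round(pts / side).astype(np.int64)
    offs = np.array([(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1)])
    cand = (cells[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    cand = np.unique(cand, axis=0)
    return cand.astype(float) * side


def _simulate_exact(cfg: GasSimConfig, rng: np.random.Generator,
                    x0: np.ndarray, phi0: np.ndarray) -> GasSimResult:
    geom = cfg.geometry
    side = float(cfg.arena_side)
    n = len(phi0)
    s_max = cfg.v * cfg.duration
    events: list[tuple[float, tuple[float, float], float]] = []
    for i in range(n):
        phi = float(phi0[i])
        intervals = _detectable_intervals(geom.theta, geom.alpha, phi)
        u = np.array([np.cos(phi), np.sin(phi)])
        centers = _candidate_centers(x0[i], u, s_max, geom.r, side)
        regions = [[None]] if intervals is None else [
            ([(a, (a + b) / 2.0), ((a + b) / 2.0, b)] if b - a > np.pi else [(a, b)])
            for a, b in intervals
        ]
        for pieces in regions:
            for j, s_in, _ in _entry_intervals(x0[i], u, s_max, geom.r, centers, pieces):
                pos = x0[i] + s_in * u - centers[j]
                events.append((s_in / cfg.v, (float(pos[0]), float(pos[1])), phi))
    events.sort(key=lambda e: e[0])
    return GasSimResult(z=len(events), events=events, realized_n=n, seed=cfg.seed)


def simulate_gas(config: GasSimConfig, method: str | None = None,
                 _chunk: int = 4096) -> GasSimResult:
    """Run the ideal-gas encounter simulation.

    An encounter requires all three of: distance to the detector at most
    r, animal inside the fixed sensor sector (centered on angle 0, width
    theta), detector inside the animal's call cone (width alpha around the
    heading).  z counts transitions *into* that state, including an animal
    already detectable at t = 0; an animal looping back is recounted,
    matching the pass-count semantics of the density formula.

    Ballistic motion (turn_rate 0) uses an exact continuous-time crossing
    count: per heading the detectable set is a union of convex circular
    sectors, intersected analytically with the straight path and its torus
    wraps, so the result has no time-discretization bias.  With
    ``turn_rate`` nonzero (or ``method="stepped"``) a fixed-step state
    machine with step ``step_dt`` is used instead.
    """
    cfg = config.resolved()
    cfg.validate()
    geom = cfg.geometry
    rng = np.random.default_rng(cfg.seed)
    side = float(cfg.arena_side)
    n = int(round(cfg.true_density * 1e-6 * side * side))
    if n == 0 or cfg.duration <= 0:
        return GasSimResult(z=0, events=[], realized_n=n, seed=cfg.seed)

    x0 = rng.uniform(-side / 2.0, side / 2.0, size=(n, 2))
    phi0 = rng.uniform(0.0, 2.0 * np.pi, size=n)
    if method is None:
        method = "exact" if cfg.turn_rate == 0.0 else "stepped"
    if method == "exact":
        if cfg.turn_rate != 0.0:
            raise ValueError("exact crossing counting requires turn_rate == 0")
        return _simulate_exact(cfg, rng, x0, phi0)
    if method != "stepped":
        raise ValueError(f"unknown method {method!r}")

    events: list[tuple[float, tuple[float, float], float]] = []
    n_steps = int(np.floor(cfg.duration / cfg.step_dt))
    r2 = geom.r**2
    half_theta = geom.theta / 2.0
    half_alpha = geom.alpha / 2.0
    omega = cfg.turn_rate

    prev_state = None
    for lo in range(0, n_steps + 1, _chunk):
        hi = min(lo + _chunk, n_steps + 1)
        t = (np.arange(lo, hi) * cfg.step_dt)[:, None]
        if omega == 0.0:
            head = np.broadcast_to(phi0, (hi - lo, n))
            disp = cfg.v * t[..., None] * np.stack([np.cos(phi0), np.sin(phi0)], axis=-1)
        else:
            head = phi0[None, :] + omega * t
            disp = (cfg.v / omega) * np.stack(
                [np.sin(head) - np.sin(phi0)[None, :],
                 -np.cos(head) + np.cos(phi0)[None, :]], axis=-1)
        pos = x0[None, :, :] + disp
        pos = (pos + side / 2.0) % side - side / 2.0

        dist2 = (pos**2).sum(axis=-1)
        psi = np.arctan2(pos[..., 1], pos[..., 0])
        to_det = np.arctan2(-pos[..., 1], -pos[..., 0])
        state = (
            (dist2 <= r2)
            & (np.abs(_wrap_angle(psi)) <= half_theta)
            & (np.abs(_wrap_angle(to_det - head)) <= half_alpha)
        )
        first = prev_state if prev_state is not None else np.zeros(n, dtype=bool)
        entered = state & ~np.vstack([first[None, :], state[:-1]])
        if prev_state is None:
            entered[0] = state[0]  # already detectable at switch-on
        for k, i in zip(*np.nonzero(entered)):
            events.append((float((lo + k) * cfg.step_dt),
                           (float(pos[k, i, 0]), float(pos[k, i, 1])),
                           float(head[k, i] if omega != 0.0 else phi0[i])))
        prev_state = state[-1]
    events.sort(key=lambda e: e[0])
    return GasSimResult(z=len(events), events=events, realized_n=n, seed=cfg.seed)


def simulate_altitude(config: GasSimConfig) -> GasSimResult:
    """Gas simulation with the flight plane a height dh above the detector.

    The detectable horizontal region shrinks to the sphere-plane
    intersection disk of radius sqrt(r^2 - dh^2); the sector and call-cone
    conditions apply unchanged in the flight plane.  ``dh = 0`` reproduces
    :func:`simulate_gas` exactly (same seed policy).
    """
    geom = config.geometry
    if geom.dh >= geom.r:
        raise ValueError("dh must be < r (else the detection disk vanishes)")
    r_eff = float(np.sqrt(geom.r**2 - geom.dh**2))
    dt_max = r_eff / (4.0 * config.v)
    dt = config.step_dt if config.step_dt is not None else r_eff / (8.0 * config.v)
    flat = dataclasses.replace(
        config,
        geometry=DetectionGeometry(r=r_eff, theta=geom.theta, alpha=geom.alpha, dh=0.0),
        arena_side=config.arena_side if config.arena_side is not None else 10.0 * geom.r,
        step_dt=min(dt, dt_max),  # the shrunken disk must stay resolved
    )
    return simulate_gas(flat)


# ---------------------------------------------------------------------------
# Royle-Nichols generator

_DET_TERMS = ("intercept", "temp", "temp2", "hum", "hum2", "slot", "slot2", "slot3", "slot4")


def simulate_rn(
    n_sites: int,
    n_occasions: int,
    abundance_coefs: Mapping[str, float],
    detection_coefs: Mapping[str, float],
    n_sessions: int | None = None,
    seed: int = 0,
) -> RnSimTruth:
    """Simulate a detection history from the Royle-Nichols generative model.

    ``abundance_coefs`` maps "(Intercept)" (log lambda at covariate means)
    and site-covariate names to log-link coefficients; covariates are drawn
    standard normal.  ``detection_coefs`` maps detection terms (intercept,
    temp, temp2, hum, hum2, slot..slot4) to logit-link coefficients;
    temperature and humidity covariates are standard normal per
    (site, occasion), the session slot is centered and scaled to [-1, 1].
    Occasions are (night, slot) pairs with ``n_sessions`` slots per night
    (default: a single night of ``n_occasions`` slots).
    """
    rng = np.random.default_rng(seed)
    s = n_sessions or n_occasions
    if n_occasions % s:
        raise ValueError("n_occasions must be a multiple of n_sessions")
    unknown = set(detection_coefs) - set(_DET_TERMS)
    if unknown:
        raise ValueError(f"unknown detection terms {sorted(unknown)}")

    cov_names = [k for k in abundance_coefs if k != "(Intercept)"]
    site_cov = pd.DataFrame(
        {name: rng.standard_normal(n_sites) for name in cov_names},
        index=[f"s{i:04d}" for i in range(n_sites)],
    )
    eta_a = np.full(n_sites, abundance_coefs.get("(Intercept)", 0.0))
    for name in cov_names:
        eta_a += abundance_coefs[name] * site_cov[name].to_numpy()
    lam = np.exp(eta_a)
    n_lat = rng.poisson(lam)

    nights = n_occasions // s
    base_date = pd.Timestamp("2016-06-01")
    occasions = [(base_date + pd.Timedelta(days=d), k)
                 for d in range(nights) for k in range(1, s + 1)]
    slot_idx = np.array([k for _, k in occasions], dtype=float)
    slot = np.zeros(n_occasions) if s == 1 else 2.0 * (slot_idx - 1.0) / (s - 1.0) - 1.0
    temp = rng.standard_normal((n_sites, n_occasions))
    hum = rng.standard_normal((n_sites, n_occasions))
    feats = {
        "intercept": np.ones((n_sites, n_occasions)),
        "temp": temp, "temp2": temp**2, "hum": hum, "hum2": hum**2,
        "slot": np.broadcast_to(slot, (n_sites, n_occasions)),
        "slot2": np.broadcast_to(slot**2, (n_sites, n_occasions)),
        "slot3": np.broadcast_to(slot**3, (n_sites, n_occasions)),
        "slot4": np.broadcast_to(slot**4, (n_sites, n_occasions)),
    }
    eta_d = np.zeros((n_sites, n_occasions))
    for term, coef in detection_coefs.items():
        eta_d = eta_d + coef * feats[term]
    r = expit(eta_d)
    with np.errstate(invalid="ignore"):
        p = 1.0 - (1.0 - r) ** n_lat[:, None]
    y = (rng.random((n_sites, n_occasions)) < p).astype(float)

    history = DetectionHistory(
        sites=list(site_cov.index),
        occasions=occasions,
        y=y,
        slot_index=slot_idx.astype(int),
        n_sessions=s,
        occ_cov={"temp": temp, "temp_missing": np.zeros_like(temp),
                 "hum": hum, "hum_missing": np.zeros_like(hum)},
        site_cov=site_cov,
        device=np.array(["dev0"] * n_sites),
    )
    return RnSimTruth(lambda_site=lam, n_site=n_lat, r_occasion=r,
                      history=history, seed=seed)


# ---------------------------------------------------------------------------
# end-to-end survey faker


def simulate_survey(
    scenario: Mapping[str, Any],
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Generate a calls/weather/sites/sun fixture set from gas simulations.

    ``scenario`` keys:

    - ``species``: mapping name -> {profile: SpeciesProfile, true_density,
      r (detection radius, m), alpha_deg}
    - ``n_sites`` (int) and optionally ``elevation_m`` (default 400)
    - ``nights``: list of dates (night start days)
    - ``theta_deg`` (default 200), ``sunset_hour`` (21), ``sunrise_hour`` (5)
    - ``temp_mean_c`` (12), ``temp_amp_c`` (3), ``rh_mean_pct`` (85)

    Every pass appears once per identification variant (strict and
    generous), mirroring the two-variant call files the readers expect.
    Returns {"calls", "weather", "sites", "sun"}; with ``out_dir`` the four
    CSV files are written and round-trip through the readers.
    """
    rng = np.random.default_rng(seed)
    n_sites = int(scenario.get("n_sites", 1))
    elev = float(scenario.get("elevation_m", 400.0))
    theta = np.deg2rad(float(scenario.get("theta_deg", 200.0)))
    sunset_h = float(scenario.get("sunset_hour", 21.0))
    sunrise_h = float(scenario.get("sunrise_hour", 5.0))
    nights = [pd.Timestamp(d) for d in scenario["nights"]]

    sun_rows = [{
        "date": night,
        "sunset": night + pd.Timedelta(hours=sunset_h),
        "sunrise": night + pd.Timedelta(hours=24 + sunrise_h),
    } for night in nights]
    sun = pd.DataFrame(sun_rows)
    duration = float((sun["sunrise"] - sun["sunset"]).dt.total_seconds().iloc[0])

    call_rows = []
    seeds = np.random.SeedSequence(seed).spawn(n_sites * len(nights) * len(scenario["species"]))
    si = 0
    for s_idx in range(n_sites):
        for night, sunset in zip(nights, sun["sunset"]):
            for name, sp in scenario["species"].items():
                geom = DetectionGeometry(
                    r=float(sp["r"]), theta=theta,
                    alpha=np.deg2rad(float(sp["alpha_deg"])),
                    dh=float(sp.get("dh", 0.0)),
                )
                cfg = GasSimConfig(
                    true_density=float(sp["true_density"]),
                    v=sp["profile"].flight_speed_v,
                    geometry=geom, duration=duration,
                    seed=int(seeds[si].generate_state(1)[0] % 2**31),
                )
                si += 1
                res = simulate_altitude(cfg) if geom.dh > 0 else simulate_gas(cfg)
                for t_ev, _, _ in res.events:
                    ts = sunset + pd.Timedelta(seconds=t_ev)
                    for variant in ("strict", "generous"):
                        call_rows.append({
                            "site_id": f"s{s_idx:03d}", "species": name,
                            "timestamp": ts, "variant": variant, "excluded": False,
                        })
    calls = pd.DataFrame(call_rows, columns=["site_id", "species", "timestamp",
                                             "variant", "excluded"])

    temp_mean = float(scenario.get("temp_mean_c", 12.0))
    temp_amp = float(scenario.get("temp_amp_c", 3.0))
    rh_mean = float(scenario.get("rh_mean_pct", 85.0))
    weather_rows = []
    for s_idx in range(n_sites):
        for night, sunset, sunrise in zip(nights, sun["sunset"], sun["sunrise"]):
            hours = pd.date_range(sunset, sunrise, freq="1h")
            frac = (hours - sunset).total_seconds() / duration
            temp = temp_mean - temp_amp * np.sin(np.pi * frac / 2.0) \
                + rng.normal(0, 0.3, len(hours))
            rh = np.clip(rh_mean + 8.0 * frac + rng.normal(0, 1.0, len(hours)), 0, 100)
            for ts, tc, rhv in zip(hours, temp, rh):
                weather_rows.append({"site_id": f"s{s_idx:03d}", "timestamp": ts,
                                     "temperature_c": round(float(tc), 2),
                                     "rh_pct": round(float(rhv), 2)})
    weather = pd.DataFrame(weather_rows)

    sites = pd.DataFrame({
        "site_id": [f"s{i:03d}" for i in range(n_sites)],
        "elevation_m": elev,
        "device_id": [f"dev{i % 3}" for i in range(n_sites)],
    })

    out = {"calls": calls, "weather": weather, "sites": sites, "sun": sun}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from .io import write_calls

        write_calls(calls, out_dir / "calls.csv")
        w = weather.copy()
        w["timestamp"] = w["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        w.to_csv(out_dir / "weather.csv", index=False)
        sites.to_csv(out_dir / "sites.csv", index=False)
        s = sun.copy()
        s["date"] = s["date"].dt.strftime("%Y-%m-%d")
        for col in ("sunset", "sunrise"):
            s[col] = s[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
        s.to_csv(out_dir / "sun.csv", index=False)
    return out
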