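"""End-to-end orchestration of the two density-estimation paths.

``run_grem_path`` chains nights -> per-night conditions -> detection radii
-> encounter-model densities over the alpha x SPL grid; ``run_rn_path``
chains session binning -> covariate selection -> detection-model AIC
selection -> the final abundance fit -> bootstrap goodness of fit ->
density.  ``compare_paths`` tabulates the two against each other and
against literature reference densities.  All stages are deterministic
given the inputs and a seed.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from . import attenuation, grem, histories, rn
from .io import Config, assign_nights, assign_periods, compute_nights, validate_calls

__all__ = ["run_grem_path", "run_rn_path", "compare_paths"]


def _prepare(calls: pd.DataFrame, sun: pd.DataFrame, config: Config):
    calls = assign_nights(calls)
    calls = assign_periods(calls, config.periods) if config.periods else calls.assign(period_id="all")
    nights = compute_nights(calls, sun)
    nights = (assign_periods(nights, config.periods) if config.periods
              else nights.assign(period_id="all"))
    calls = validate_calls(calls, nights)
    return calls, nights


def run_grem_path(
    calls: pd.DataFrame,
    weather: pd.DataFrame,
    sites: pd.DataFrame,
    sun: pd.DataFrame,
    config: Config,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """gREM path: per (species, period, variant, alpha, SPL) densities plus
    the per species x variant averaged summary."""
    calls, nights = _prepare(calls, sun, config)
    spl_step = float(config.settings.get("spl_step_db", 10.0))
    conds = attenuation.night_conditions(nights, weather, sites)
    grids = []
    for name, profile in config.species.items():
        sub = calls[calls["species"] == name]
        if sub.empty:
            continue
        ranges = attenuation.ranges_for_nights(profile, config.detector, conds, spl_step)
        grids.append(grem.estimate_grid(sub, nights, profile, config.detector, ranges))
    grid = pd.concat(grids, ignore_index=True) if grids else pd.DataFrame(
        columns=["species", "period_id", "variant", "alpha_deg", "spl_db",
                 "r_m", "p_bar_m", "z", "t_s", "density_per_km2"])
    summary = grem.summarize_grem(grid) if len(grid) else pd.DataFrame(
        columns=["species", "variant", "mean_density_per_km2"])
    return grid, summary


def run_rn_path(
    calls: pd.DataFrame,
    weather: pd.DataFrame,
    sites: pd.DataFrame,
    sun: pd.DataFrame,
    config: Config,
    seed: int = 0,
) -> pd.DataFrame:
    """Royle-Nichols path per species x period x variant.

    Settings used (config.settings): ``n_boot`` (default 2000),
    ``rn_top_k`` site covariates after pruning (default 5),
    ``detection_candidates`` ("full" nested family or "minimal"
    intercept/slot/temp designs).  Non-convergence in one cell is reported
    without aborting the others.  Returns a tidy frame with mean lambda,
    GOF p-value, c-hat and the (possibly withheld) density.
    """
    calls, nights = _prepare(calls, sun, config)
    n_boot = int(config.settings.get("n_boot", 2000))
    top_k = int(config.settings.get("rn_top_k", 5))
    cand_mode = config.settings.get("detection_candidates", "minimal")
    candidates = (rn.default_candidates() if cand_mode == "full"
                  else [rn.DetectionDesign.from_orders(),
                        rn.DetectionDesign.from_orders(slot=1),
                        rn.DetectionDesign.from_orders(temp=1),
                        rn.DetectionDesign.from_orders(temp=1, slot=1)])

    rows = []
    calls_ok = calls[~calls["excluded"]]
    for name, profile in config.species.items():
        sp_calls = calls_ok[calls_ok["species"] == name]
        for period in sorted(sp_calls["period_id"].dropna().unique()):
            p_nights = nights.merge(
                calls[calls["period_id"] == period][["site_id", "night_id"]].drop_duplicates(),
                on=["site_id", "night_id"])
            for variant in ("strict", "generous"):
                sub = sp_calls[(sp_calls["period_id"] == period)
                               & (sp_calls["variant"] == variant)]
                try:
                    row = _fit_cell(sub, p_nights, sites, weather, profile,
                                    candidates, top_k, n_boot, seed)
                except (ValueError, RuntimeError) as exc:
                    warnings.warn(f"{name}/{period}/{variant}: {exc}")
                    row = {"converged": False, "density_per_km2": None,
                           "note": str(exc)}
                row.update({"species": name, "period_id": period, "variant": variant})
                rows.append(row)
    return pd.DataFrame(rows)


def _fit_cell(sub, p_nights, sites, weather, profile, candidates, top_k, n_boot, seed):
    merged = sub.merge(p_nights, on=["site_id", "night_id"])
    times = [histories.normalize_time(r["timestamp"], r["sunset"], r["sunrise"])
             for _, r in merged.iterrows()]
    grid = histories.scott_session_count(times)
    hist = histories.build_history(sub, p_nights, grid, sites, weather)

    selected: list[str] = []
    numeric = hist.site_cov.select_dtypes(include=[np.number])
    if numeric.shape[1] and top_k > 0:
        response = np.nansum(hist.y, axis=1)
        ranking = rn.rank_site_covariates(numeric, response, seed=seed)
        if len(ranking):
            kept = rn.prune_correlated(ranking["covariate"], numeric)
            selected = kept[:top_k]

    table = rn.select_detection_model(hist, candidates, seed=seed)
    if table.empty:
        raise RuntimeError("no fittable detection design")
    best = table.iloc[0]["design"]
    fit = rn.fit_rn(hist, best, selected, seed=seed)
    if not fit.converged:
        return {"n_sessions": grid.n_sessions, "detection_design": best.label(),
                "converged": False, "density_per_km2": None, "note": "non-convergence"}
    gof = rn.mb_gof(fit, hist, n_boot=n_boot, seed=seed)
    est = rn.rn_density(fit, profile, gof)
    return {
        "n_sessions": grid.n_sessions,
        "detection_design": best.label(),
        "site_covariates": ",".join(selected),
        "mean_lambda": fit.mean_lambda,
        "aic": fit.aic,
        "converged": True,
        "gof_p": gof.p_value,
        "c_hat": gof.c_hat,
        "gof_pass": est.gof_pass,
        "density_per_km2": est.density,
    }


def compare_paths(
    grem_summary: pd.DataFrame,
    rn_table: pd.DataFrame,
    literature: dict[str, float] | None = None,
) -> pd.DataFrame:
    """RN / gREM density ratios per species and variant, with literature
    reference densities where configured.  Missing sides yield flagged
    partial rows rather than errors."""
    lit = literature or {}
    rn_ok = rn_table[rn_table.get("density_per_km2").notna()] if len(rn_table) else rn_table
    rn_mean = (rn_ok.groupby(["species", "variant"])["density_per_km2"].mean()
               if len(rn_ok) else pd.Series(dtype=float))
    rows = []
    species = set(grem_summary.get("species", [])) | set(rn_table.get("species", []))
    for sp in sorted(species):
        for variant in ("strict", "generous"):
            g = grem_summary.query("species == @sp and variant == @variant")
            g_val = float(g["mean_density_per_km2"].iloc[0]) if len(g) else np.nan
            r_val = float(rn_mean.get((sp, variant), np.nan))
            rows.append({
                "species": sp, "variant": variant,
                "grem_density_per_km2": g_val,
                "rn_density_per_km2": r_val,
                "rn_to_grem_ratio": r_val / g_val if g_val and np.isfinite(g_val) else np.nan,
                "literature_density_per_km2": lit.get(sp, np.nan),
                "partial": not (np.isfinite(g_val) and np.isfinite(r_val)),
            })
    return pd.DataFrame(rows)
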