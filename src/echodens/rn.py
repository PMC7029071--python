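"""Royle-Nichols abundance model, implemented from its likelihood.

Latent site abundance N_i ~ Poisson(lambda_i) links repeated
detection/nondetection data y_ij to abundance through the per-visit
detection probability

    p_ij = 1 - (1 - r_ij)^N_i

with r_ij the single-individual detection probability (logit link on
occasion covariates) and lambda_i on a log link of site covariates.
The site likelihood marginalizes N over 0..K with K chosen so the Poisson
tail mass beyond K is below 1e-8.

The module also covers the surrounding workflow: random-forest ranking of
site covariates with correlation pruning, AIC selection among nested
detection designs, the MacKenzie-Bailey parametric-bootstrap goodness of
fit with overdispersion ratio c-hat, and density from mean lambda and
median home-range area.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp
from scipy.stats import poisson, spearmanr

from .histories import DetectionHistory
from .io import SpeciesProfile

__all__ = [
    "DetectionDesign",
    "RNFit",
    "GofResult",
    "RnDensityEstimate",
    "rn_detection_prob",
    "truncation_bound",
    "site_marginal_likelihood",
    "fit_rn",
    "select_detection_model",
    "rank_site_covariates",
    "prune_correlated",
    "mb_gof",
    "rn_density",
    "lambda_wald_ci",
]

TAIL_MASS = 1e-8
K_FLOOR = 50

_POLY = {"temp": ("temp", "temp2"), "hum": ("hum", "hum2"),
         "slot": ("slot", "slot2", "slot3", "slot4")}
_ORDER = ["intercept", "temp", "temp2", "hum", "hum2",
          "slot", "slot2", "slot3", "slot4", "device"]


@dataclasses.dataclass(frozen=True)
class DetectionDesign:
    """Ordered detection-covariate terms (always includes the intercept).

    Valid terms: intercept, temp, temp2, hum, hum2, slot, slot2, slot3,
    slot4, device.  Polynomial terms require all lower orders.
    """

    terms: tuple[str, ...] = ("intercept",)

    def __post_init__(self) -> None:
        unknown = set(self.terms) - set(_ORDER)
        if unknown:
            raise ValueError(f"unknown detection terms {sorted(unknown)}")
        if "intercept" not in self.terms:
            raise ValueError("the intercept term is mandatory")
        for base, chain in _POLY.items():
            for lo, hi in zip(chain, chain[1:]):
                if hi in self.terms and lo not in self.terms:
                    raise ValueError(f"term {hi} requires {lo}")

    @classmethod
    def from_orders(cls, temp: int = 0, hum: int = 0, slot: int = 0,
                    device: bool = False) -> "DetectionDesign":
        terms = ["intercept"]
        terms += list(_POLY["temp"][:temp]) + list(_POLY["hum"][:hum])
        terms += list(_POLY["slot"][:slot])
        if device:
            terms.append("device")
        return cls(tuple(t for t in _ORDER if t in terms))

    def label(self) -> str:
        return "+".join(self.terms)


@dataclasses.dataclass
class RNFit:
    """A fitted Royle-Nichols model."""

    det_terms: tuple[str, ...]
    det_names: list[str]
    det_coefs: np.ndarray
    ab_names: list[str]
    ab_coefs: np.ndarray
    lambda_site: np.ndarray
    mean_lambda: float
    K: int
    loglik: float
    aic: float
    converged: bool
    vcov: np.ndarray | None = dataclasses.field(default=None, repr=False)
    _y: np.ndarray | None = dataclasses.field(default=None, repr=False)
    _Xd: np.ndarray | None = dataclasses.field(default=None, repr=False)
    _Xa: np.ndarray | None = dataclasses.field(default=None, repr=False)

    @property
    def n_params(self) -> int:
        return len(self.det_coefs) + len(self.ab_coefs)

    @property
    def r_matrix(self) -> np.ndarray:
        """Fitted single-individual detection probabilities (sites x occasions)."""
        from scipy.special import expit

        return expit(np.einsum("ijp,p->ij", self._Xd, self.det_coefs))


@dataclasses.dataclass
class GofResult:
    """MacKenzie-Bailey parametric-bootstrap goodness of fit."""

    chi2_observed: float
    chi2_bootstrap: np.ndarray
    p_value: float
    c_hat: float
    n_boot: int
    n_failed: int = 0


@dataclasses.dataclass
class RnDensityEstimate:
    """Density from mean lambda over median MCP home-range area.

    ``density`` is withheld (None) when the goodness of fit rejects the
    model at the 5% level.
    """

    species: str
    period_id: str
    variant: str
    mean_lambda: float
    home_range_area: float
    density: float | None
    gof_pass: bool


# ---------------------------------------------------------------------------
# likelihood primitives


def rn_detection_prob(r_ij: float, n: int) -> float:
    """Per-visit detection probability 1 - (1 - r)^N at abundance N."""
    r = np.asarray(r_ij, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("r_ij must lie in [0, 1]")
    if np.any(np.asarray(n) < 0):
        raise ValueError("N must be >= 0")
    out = 1.0 - (1.0 - r) ** np.asarray(n)
    return float(out) if np.isscalar(r_ij) and np.isscalar(n) else out


def truncation_bound(lam: float, floor: int = K_FLOOR, tail: float = TAIL_MASS) -> int:
    """Smallest K with Poisson tail mass beyond K below ``tail`` (floored)."""
    k = int(poisson.isf(tail, max(lam, 1e-12)))
    return max(k + 1, floor)


def site_marginal_likelihood(
    y_i: Sequence[float],
    r_i: Sequence[float],
    lambda_i: float,
    K: int | None = None,
) -> float:
    """Marginal likelihood of one site's history under the RN mixture.

    Sums Poisson(N; lambda) * prod_j p_ij^y (1-p_ij)^(1-y) over N = 0..K,
    with p_ij = 1 - (1 - r_ij)^N.  Missing occasions (NaN in ``y_i``) are
    skipped.  A user-supplied K leaving more than 1e-8 Poisson tail mass is
    raised automatically with a warning.
    """
    y = np.asarray(y_i, dtype=float)
    r = np.asarray(r_i, dtype=float)
    if lambda_i <= 0:
        raise ValueError("lambda_i must be positive")
    k_needed = truncation_bound(lambda_i)
    if K is None:
        K = k_needed
    elif K < k_needed:
        warnings.warn(f"K={K} leaves Poisson tail mass above {TAIL_MASS}; raised to {k_needed}")
        K = k_needed
    obs = ~np.isnan(y)
    y, r = y[obs], r[obs]
    n = np.arange(K + 1)
    log_pois = n * np.log(lambda_i) - lambda_i - gammaln(n + 1)
    a = n[:, None] * np.log1p(-r)[None, :]  # log(1-p) per (N, j)
    with np.errstate(divide="ignore"):
        log_p = np.log(-np.expm1(a))
    contrib = np.where(y == 1, log_p, a).sum(axis=1)
    return float(np.exp(logsumexp(log_pois + contrib)))


# ---------------------------------------------------------------------------
# design construction


def _scaled_slot(history: DetectionHistory) -> np.ndarray:
    s = history.n_sessions
    slot = history.slot_index.astype(float)
    if s == 1:
        return np.zeros_like(slot)
    return 2.0 * (slot - 1.0) / (s - 1.0) - 1.0  # centered and scaled to [-1, 1]


def build_detection_design(history: DetectionHistory, design: DetectionDesign):
    """(n_sites, n_occasions, P) detection design tensor plus column names."""
    n_i, n_j = history.y.shape
    slot = np.broadcast_to(_scaled_slot(history), (n_i, n_j))
    base = {
        "intercept": np.ones((n_i, n_j)),
        "temp": history.occ_cov["temp"],
        "temp2": history.occ_cov["temp"] ** 2,
        "hum": history.occ_cov["hum"],
        "hum2": history.occ_cov["hum"] ** 2,
        "slot": slot, "slot2": slot**2, "slot3": slot**3, "slot4": slot**4,
    }
    cols, names = [], []
    for term in design.terms:
        if term == "device":
            levels, counts = np.unique(history.device, return_counts=True)
            ref = levels[np.argmax(counts)]
            for lev in levels:
                if lev == ref:
                    continue
                cols.append(np.broadcast_to((history.device == lev).astype(float)[:, None],
                                            (n_i, n_j)))
                names.append(f"device[{lev}]")
        else:
            cols.append(base[term])
            names.append(term)
    return np.stack(cols, axis=-1).astype(float), names


def build_abundance_design(history: DetectionHistory, covariates: Sequence[str]):
    """(n_sites, 1 + Q) abundance design matrix (intercept first)."""
    n_i = len(history.sites)
    cols = [np.ones(n_i)]
    names = ["(Intercept)"]
    for name in covariates:
        if name not in history.site_cov.columns:
            raise KeyError(f"site covariate {name!r} not in history")
        cols.append(history.site_cov[name].to_numpy(dtype=float))
        names.append(name)
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# negative log likelihood (vectorized; fast path for intercept-only models)


def _nll_factory(y: np.ndarray, Xd: np.ndarray, Xa: np.ndarray):
    n_i, n_j, p = Xd.shape
    q = Xa.shape[1]
    w1 = y == 1
    w0 = y == 0
    n_occ = (~np.isnan(y)).sum(axis=1)

    fast = (
        p == 1 and q == 1
        and not np.isnan(y).any()
        and np.ptp(Xd) == 0.0
    )
    if fast:
        k_det = np.nansum(y, axis=1)
        uniq, mult = np.unique(k_det, return_counts=True)
        j_tot = float(n_j)

        def nll(params: np.ndarray) -> float:
            logf = _log_count_prob(np.asarray([params[0]]), np.asarray([params[1]]),
                                   int(j_tot))[0]
            return float(-(mult * logf[uniq.astype(int)]).sum())

        return nll

    def nll(params: np.ndarray) -> float:
        beta_d, beta_a = params[:p], params[p:]
        eta_d = np.einsum("ijp,p->ij", Xd, beta_d)
        log1mr = -np.logaddexp(0.0, eta_d)
        lam = np.exp(np.clip(Xa @ beta_a, -30.0, 10.0))
        K = _runtime_k(float(lam.max()))
        n = np.arange(K + 1)
        log_pois = (n[:, None] * np.log(lam)[None, :] - lam[None, :]
                    - gammaln(n + 1)[:, None])
        a = n[:, None, None] * log1mr[None, :, :]
        with np.errstate(divide="ignore"):
            log_p = np.log(-np.expm1(a))
        contrib = (np.where(w1[None], log_p, 0.0) + np.where(w0[None], a, 0.0)).sum(axis=2)
        ll = logsumexp(log_pois + contrib, axis=0)
        # all-missing sites contribute nothing
        return float(-ll[n_occ > 0].sum())

    return nll


def _runtime_k(lam_max: float) -> int:
    # Gaussian-tail style bound, always >= the exact 1e-8 quantile in practice
    return int(max(K_FLOOR, np.ceil(lam_max + 12.0 * np.sqrt(lam_max + 1.0) + 10.0)))


def _tight_k(lam_max: float) -> int:
    """Smallest K with Poisson tail below the truncation tolerance (no floor;
    used in the batched bootstrap path where the extra floor-50 headroom of
    the public likelihood would triple the flop count for small lambda)."""
    return int(poisson.isf(TAIL_MASS, max(lam_max, 1e-12))) + 2


def _log_count_prob(eta_d: np.ndarray, eta_a: np.ndarray, n_occ: int,
                    tight: bool = False) -> np.ndarray:
    """log P(one specific length-J history with k detections), (B, J+1).

    Valid when the individual detection probability r is constant within a
    dataset: the probability of a specific binary history depends on its
    detection count k only,
    P(k) = sum_N Poisson(N; lambda) * p_N^k * (1 - r)^(N (J - k)).
    Vectorized over B (eta_d, eta_a) parameter pairs.
    """
    eta_d = np.clip(eta_d, -30.0, 30.0)
    lam = np.exp(np.clip(eta_a, -30.0, 10.0))
    logq = -np.logaddexp(0.0, eta_d)  # log(1 - r)
    K = _tight_k(float(lam.max())) if tight else _runtime_k(float(lam.max()))
    n = np.arange(K + 1)
    log_pois = n[None, :] * np.log(lam)[:, None] - lam[:, None] - gammaln(n + 1)[None, :]
    a = n[None, :] * logq[:, None]  # (B, K+1) = log(1-p_N)
    with np.errstate(divide="ignore"):
        log_p = np.log(-np.expm1(a))
    log_p = np.maximum(log_p, -745.0)  # keep 0 * (-inf) out of the algebra
    k = np.arange(n_occ + 1)
    m = (log_pois[:, :, None]
         + log_p[:, :, None] * k[None, None, :]
         + a[:, :, None] * (n_occ - k)[None, None, :])
    return logsumexp(m, axis=1)  # (B, J+1)


def _fit_intercepts_batch(
    hists: np.ndarray, n_occ: int, start: np.ndarray,
    max_iter: int = 40, tol: float = 1e-7,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched intercept-only RN maximum likelihood via damped Newton.

    ``hists`` is (B, J+1): per dataset the histogram of per-site detection
    counts.  All B likelihoods are maximized simultaneously with
    finite-difference gradients/Hessians of the 2-parameter profile
    (detection logit, log lambda).  Returns (eta_d, eta_a, converged).
    """
    b = hists.shape[0]
    theta = np.tile(start.astype(float), (b, 1))
    h = 1e-5

    def nll(th: np.ndarray, hh: np.ndarray) -> np.ndarray:
        logf = _log_count_prob(th[:, 0], th[:, 1], n_occ, tight=True)
        return -(hh * logf).sum(axis=1)

    # 6-point finite-difference stencil, evaluated in one stacked call
    stencil = np.array([[0.0, 0.0], [h, 0.0], [-h, 0.0],
                        [0.0, h], [0.0, -h], [h, h]])

    active = np.ones(b, dtype=bool)
    grad = np.zeros((b, 2))
    for _ in range(max_iter):
        if not active.any():
            break
        th = theta[active]
        hh = hists[active]
        m = len(th)
        pts = (th[None, :, :] + stencil[:, None, :]).reshape(-1, 2)
        vals = nll(pts, np.tile(hh, (len(stencil), 1))).reshape(len(stencil), m)
        f0, fp1, fm1, fp2, fm2, fpp = vals
        g = np.stack([(fp1 - fm1) / (2 * h), (fp2 - fm2) / (2 * h)], axis=1)
        grad[active] = g
        d11 = (fp1 - 2 * f0 + fm1) / h**2
        d22 = (fp2 - 2 * f0 + fm2) / h**2
        d12 = (fpp - fp1 - fp2 + f0) / h**2
        det = d11 * d22 - d12**2
        pd = (det > 1e-12) & (d11 > 0)
        step = np.zeros_like(g)
        step[pd, 0] = (d22[pd] * g[pd, 0] - d12[pd] * g[pd, 1]) / det[pd]
        step[pd, 1] = (d11[pd] * g[pd, 1] - d12[pd] * g[pd, 0]) / det[pd]
        step[~pd] = np.sign(g[~pd]) * 0.5  # gradient step when Hessian not PD
        step = np.clip(step, -2.0, 2.0)
        new = th - step
        f_new = nll(new, hh)
        worse = f_new > f0 + 1e-12
        for _ in range(8):  # backtracking for the few non-descending rows
            if not worse.any():
                break
            step[worse] *= 0.5
            new[worse] = th[worse] - step[worse]
            f_new[worse] = nll(new[worse], hh[worse])
            worse = f_new > f0 + 1e-12
        theta[active] = np.clip(new, -15.0, 15.0)
        done = np.max(np.abs(g), axis=1) < tol * np.maximum(1.0, np.abs(f0))
        idx = np.nonzero(active)[0]
        active[idx[done]] = False
    converged = np.max(np.abs(grad), axis=1) < 100 * tol * np.maximum(
        1.0, np.abs(nll(theta, hists)))
    return theta[:, 0], theta[:, 1], converged


# ---------------------------------------------------------------------------
# fitting


def fit_rn(
    history: DetectionHistory,
    detection_design: DetectionDesign | None = None,
    abundance_covariates: Sequence[str] = (),
    n_restarts: int = 5,
    seed: int = 0,
    start: np.ndarray | None = None,
) -> RNFit:
    """Maximum-likelihood Royle-Nichols fit.

    Quasi-Newton (L-BFGS-B) minimization of the summed negative log
    marginal likelihood, with ``n_restarts`` random restarts (fixed seed
    stream) because RN likelihoods can be multimodal on small data.  The
    fit is flagged converged when the gradient infinity-norm is small and,
    with several restarts, the best two agree in log likelihood.
    """
    design = detection_design or DetectionDesign()
    Xd, det_names = build_detection_design(history, design)
    Xa, ab_names = build_abundance_design(history, abundance_covariates)
    y = history.y
    if (~np.isnan(y)).sum() == 0 or len(history.sites) < 2:
        raise ValueError("need >= 2 sites with at least one surveyed occasion")
    if np.nansum(y) == 0:
        warnings.warn("all-zero detection history; lambda is at its lower boundary")
    nll = _nll_factory(y, Xd, Xa)
    p, q = Xd.shape[2], Xa.shape[1]

    rng = np.random.default_rng(seed)
    naive = np.nanmean(y) if np.nansum(y) > 0 else 0.01
    base = np.zeros(p + q)
    base[0] = np.log(naive / (1 - naive + 1e-12))  # detection intercept
    base[p] = 0.0  # log lambda intercept
    starts: list[np.ndarray] = []
    if start is not None:
        starts.append(np.asarray(start, dtype=float))
    starts.append(base)
    while len(starts) < n_restarts:
        starts.append(base + rng.normal(scale=0.75, size=p + q))

    results = []
    for x0 in starts:
        try:
            res = minimize(nll, x0, method="L-BFGS-B",
                           options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-8})
            if np.isfinite(res.fun):
                results.append(res)
        except (FloatingPointError, ValueError):  # pragma: no cover - rare
            continue
    if not results:
        raise RuntimeError("all optimizer restarts failed")
    results.sort(key=lambda r: r.fun)
    best = results[0]
    grad_ok = np.max(np.abs(best.jac)) < 1e-3 * max(1.0, abs(best.fun))
    agree = True
    if len(results) >= 2:
        agree = (results[1].fun - best.fun) < 1e-3 or np.allclose(
            results[1].x, best.x, atol=1e-3)
    converged = bool(grad_ok and (agree or len(results) < 2))

    beta_d, beta_a = best.x[:p], best.x[p:]
    lam = np.exp(Xa @ beta_a)
    loglik = -best.fun
    n_par = p + q
    fit = RNFit(
        det_terms=design.terms, det_names=det_names, det_coefs=beta_d,
        ab_names=ab_names, ab_coefs=beta_a, lambda_site=lam,
        mean_lambda=float(lam.mean()), K=_runtime_k(float(lam.max())),
        loglik=loglik, aic=-2.0 * loglik + 2.0 * n_par, converged=converged,
        _y=y, _Xd=Xd, _Xa=Xa,
    )
    fit.vcov = _wald_vcov(nll, best.x)
    return fit


def _wald_vcov(nll, x: np.ndarray, h: float = 1e-4) -> np.ndarray | None:
    """Observed-information covariance via central-difference Hessian."""
    n = x.size
    hess = np.empty((n, n))
    f0 = nll(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            fpp = nll(x + ei + ej)
            fpm = nll(x + ei - ej)
            fmp = nll(x - ei + ej)
            fmm = nll(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)):
        return None
    return cov


def lambda_wald_ci(fit: RNFit, level: float = 0.95) -> tuple[float, float]:
    """Wald interval for the abundance intercept's lambda (exp scale)."""
    from scipy.stats import norm

    if fit.vcov is None:
        raise ValueError("fit has no covariance matrix")
    i = len(fit.det_coefs)  # abundance intercept index
    se = np.sqrt(fit.vcov[i, i])
    zq = norm.ppf(0.5 + level / 2)
    c = fit.ab_coefs[0]
    return float(np.exp(c - zq * se)), float(np.exp(c + zq * se))


# ---------------------------------------------------------------------------
# model and covariate selection


def default_candidates() -> list[DetectionDesign]:
    """Nested detection-design family: temperature and humidity orders 0-2,
    session-slot orders 0-4, device identity on/off."""
    out = []
    for t, h, s, d in itertools.product(range(3), range(3), range(5), (False, True)):
        out.append(DetectionDesign.from_orders(temp=t, hum=h, slot=s, device=d))
    return out


def select_detection_model(
    history: DetectionHistory,
    candidates: Sequence[DetectionDesign] | None = None,
    n_restarts: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """AIC table over candidate detection designs (intercept-only abundance).

    The winner (lowest AIC) is intended for the final fit with site
    covariates; unfittable candidates are skipped with a warning.
    """
    cands = list(candidates) if candidates is not None else default_candidates()
    rows = []
    for design in cands:
        try:
            fit = fit_rn(history, design, (), n_restarts=n_restarts, seed=seed)
        except (RuntimeError, ValueError) as exc:
            warnings.warn(f"candidate {design.label()} unfittable: {exc}")
            continue
        rows.append({"design": design, "label": design.label(),
                     "n_params": fit.n_params, "loglik": fit.loglik,
                     "aic": fit.aic, "converged": fit.converged})
    table = pd.DataFrame(rows).sort_values("aic", kind="mergesort").reset_index(drop=True)
    if not table.empty:
        table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return table


def rank_site_covariates(
    site_covariates: pd.DataFrame,
    response: Sequence[float],
    mtry: int = 18,
    ntree_start: int = 500,
    stability: float = 0.95,
    max_ntree: int = 16000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-importance ranking of site covariates via random forest.

    The response is the per-site number of sessions with detections.
    ``mtry`` maps to the forest's max_features (capped at the covariate
    count).  The tree count starts at ``ntree_start`` and doubles until
    the Spearman correlation between successive importance rankings
    reaches ``stability``.
    """
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.inspection import permutation_importance

    y = np.asarray(response, dtype=float)
    x = site_covariates.select_dtypes(include=[np.number])
    if np.ptp(y) == 0:
        warnings.warn("constant response; no covariate ranking possible")
        return pd.DataFrame(columns=["covariate", "importance"])

    def importances(ntree: int) -> np.ndarray:
        rf = RandomForestRegressor(
            n_estimators=ntree, max_features=min(mtry, x.shape[1]),
            random_state=seed, n_jobs=1,
        ).fit(x, y)
        pi = permutation_importance(rf, x, y, n_repeats=10, random_state=seed, n_jobs=1)
        return pi.importances_mean

    ntree = ntree_start
    prev = importances(ntree)
    while ntree < max_ntree:
        ntree *= 2
        cur = importances(ntree)
        rho = spearmanr(prev, cur).statistic if x.shape[1] > 1 else 1.0
        prev = cur
        if rho >= stability:
            break
    order = np.argsort(prev)[::-1]
    return pd.DataFrame({"covariate": x.columns[order], "importance": prev[order]})


def prune_correlated(
    ranked_names: Sequence[str],
    covariates: pd.DataFrame,
    threshold: float = 0.6,
) -> list[str]:
    """Greedy correlation pruning in importance order.

    Scanning from the most important covariate down, a covariate is kept
    unless its absolute Pearson correlation with an already-kept covariate
    exceeds ``threshold``.
    """
    kept: list[str] = []
    for name in ranked_names:
        x = covariates[name].to_numpy(dtype=float)
        ok = True
        for other in kept:
            rho = np.corrcoef(x, covariates[other].to_numpy(dtype=float))[0, 1]
            if abs(rho) > threshold:
                ok = False
                break
        if ok:
            kept.append(name)
    return kept


# ---------------------------------------------------------------------------
# goodness of fit


def _history_chi2(y: np.ndarray, r: np.ndarray, lam: np.ndarray) -> float:
    """MacKenzie-Bailey chi-square over distinct detection histories.

    Sites are grouped into cohorts sharing a missingness pattern; within a
    cohort the expected frequency of each observed distinct history is the
    sum over sites of its model probability (N marginalized).  Probability
    mass on unobserved histories enters as a remainder cell with O = 0.
    """
    miss = np.isnan(y)
    chi2 = 0.0
    patterns = np.unique(miss, axis=0)
    for pat in patterns:
        rows = np.where((miss == pat).all(axis=1))[0]
        obs_cols = ~pat
        if obs_cols.sum() == 0:
            continue
        sub_y = y[np.ix_(rows, obs_cols)]
        sub_r = r[np.ix_(rows, obs_cols)]
        sub_lam = lam[rows]
        K = _runtime_k(float(sub_lam.max()))
        n = np.arange(K + 1)
        log_pois = (n[:, None] * np.log(sub_lam)[None, :] - sub_lam[None, :]
                    - gammaln(n + 1)[:, None])
        a = n[:, None, None] * np.log1p(-sub_r)[None, :, :]
        with np.errstate(divide="ignore"):
            log_p = np.log(-np.expm1(a))
        hist, counts = np.unique(sub_y, axis=0, return_counts=True)
        e_total = 0.0
        for h, o_h in zip(hist, counts):
            w1 = h == 1
            contrib = (np.where(w1[None, None, :], log_p, a)).sum(axis=2)
            prob = np.exp(logsumexp(log_pois + contrib, axis=0))
            e_h = float(prob.sum())
            e_total += e_h
            if e_h > 0:
                chi2 += (o_h - e_h) ** 2 / e_h
        e_rem = max(len(rows) - e_total, 0.0)
        chi2 += e_rem
    return chi2


def mb_gof(
    fit: RNFit,
    history: DetectionHistory | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> GofResult:
    """Parametric-bootstrap goodness of fit with overdispersion ratio c-hat.

    Simulates ``n_boot`` datasets from the fitted model, refits each (warm
    start at the parent estimates) and recomputes the history chi-square;
    the p-value is the bootstrap proportion at or above the observed
    statistic and c_hat the observed-to-mean ratio.  Refit failures are
    dropped and counted.
    """
    if not fit.converged:
        warnings.warn("goodness of fit on a non-converged fit")
    y, Xd, Xa = fit._y, fit._Xd, fit._Xa
    r = fit.r_matrix
    lam = fit.lambda_site
    rng = np.random.default_rng(seed)
    start = np.concatenate([fit.det_coefs, fit.ab_coefs])

    fast = (Xd.shape[2] == 1 and Xa.shape[1] == 1 and not np.isnan(y).any()
            and np.ptp(Xd) == 0.0)
    if fast:
        return _gof_fast(y, start, n_boot, rng)

    chi2_obs = _history_chi2(y, r, lam)
    miss = np.isnan(y)
    boots = []
    failed = 0
    for _ in range(n_boot):
        n_lat = rng.poisson(lam)
        p_det = -np.expm1(n_lat[:, None] * np.log1p(-r))
        y_b = (rng.random(y.shape) < p_det).astype(float)
        y_b[miss] = np.nan
        try:
            refit = _refit(y_b, Xd, Xa, start)
            boots.append(_history_chi2(y_b, refit["r"], refit["lam"]))
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            failed += 1
    boots = np.asarray(boots)
    if boots.size == 0:
        raise RuntimeError("every bootstrap refit failed")
    p_val = float(np.mean(boots >= chi2_obs))
    return GofResult(
        chi2_observed=chi2_obs, chi2_bootstrap=boots, p_value=p_val,
        c_hat=float(chi2_obs / boots.mean()), n_boot=int(boots.size),
        n_failed=failed,
    )


def _chi2_counts(codes: np.ndarray, k_sites: np.ndarray, logf_row: np.ndarray,
                 n_sites: int) -> float:
    """Distinct-history chi-square when P(history) depends on its count only."""
    uniq, first, counts = np.unique(codes, return_index=True, return_counts=True)
    e = n_sites * np.exp(logf_row[k_sites[first].astype(int)])
    chi2 = float(((counts - e) ** 2 / e).sum())
    return chi2 + max(n_sites - float(e.sum()), 0.0)


def _gof_fast(y: np.ndarray, start: np.ndarray, n_boot: int,
              rng: np.random.Generator, chunk: int = 256) -> GofResult:
    """Constant-r, intercept-only bootstrap with all refits batched."""
    n_sites, n_occ = y.shape
    powers = 1 << np.arange(n_occ, dtype=np.int64)
    bits = y > 0.5
    codes = bits @ powers
    k_sites = bits.sum(axis=1)
    # refit the observed data through the same batched Newton as the
    # bootstrap replicates so both sides sit at comparable optima
    hist0 = (k_sites[None, :, None] == np.arange(n_occ + 1)[None, None, :]).sum(axis=1)
    ed0, ea0, _ = _fit_intercepts_batch(hist0, n_occ, start)
    logf0 = _log_count_prob(ed0, ea0, n_occ, tight=True)[0]
    chi2_obs = _chi2_counts(codes, k_sites, logf0, n_sites)

    q = float(1.0 / (1.0 + np.exp(ed0[0])))  # 1 - r at the MLE
    lam = float(np.exp(ea0[0]))
    boots: list[float] = []
    failed = 0
    for lo in range(0, n_boot, chunk):
        b = min(chunk, n_boot - lo)
        n_lat = rng.poisson(lam, size=(b, n_sites))
        p_det = 1.0 - q**n_lat
        y_b = rng.random((b, n_sites, n_occ)) < p_det[:, :, None]
        k_b = y_b.sum(axis=2)
        codes_b = y_b @ powers
        hists = (k_b[:, :, None] == np.arange(n_occ + 1)[None, None, :]).sum(axis=1)
        eta_d, eta_a, conv = _fit_intercepts_batch(hists, n_occ, start)
        logf = _log_count_prob(eta_d, eta_a, n_occ, tight=True)
        # non-converged rows sit on the weak-identifiability ridge or a
        # boundary; their fitted history probabilities are still valid, so
        # they stay in the reference distribution (dropping them would
        # thin the tail).  Only non-finite results are discarded.
        for i in range(b):
            c2 = _chi2_counts(codes_b[i], k_b[i], logf[i], n_sites)
            if np.isfinite(c2):
                boots.append(c2)
            else:
                failed += 1
    boots_arr = np.asarray(boots)
    if boots_arr.size == 0:
        raise RuntimeError("every bootstrap refit failed")
    return GofResult(
        chi2_observed=chi2_obs, chi2_bootstrap=boots_arr,
        p_value=float(np.mean(boots_arr >= chi2_obs)),
        c_hat=float(chi2_obs / boots_arr.mean()), n_boot=int(boots_arr.size),
        n_failed=failed,
    )


def _refit(y: np.ndarray, Xd: np.ndarray, Xa: np.ndarray, start: np.ndarray) -> dict:
    from scipy.special import expit

    nll = _nll_factory(y, Xd, Xa)
    res = minimize(nll, start, method="L-BFGS-B",
                   options={"maxiter": 300, "ftol": 1e-10, "gtol": 1e-7})
    if not np.isfinite(res.fun):
        raise RuntimeError("bootstrap refit diverged")
    p = Xd.shape[2]
    beta_d, beta_a = res.x[:p], res.x[p:]
    return {
        "r": expit(np.einsum("ijp,p->ij", Xd, beta_d)),
        "lam": np.exp(np.clip(Xa @ beta_a, -30, 10)),
    }


# ---------------------------------------------------------------------------
# density


def rn_density(
    fit: RNFit,
    profile: SpeciesProfile,
    gof: GofResult,
    period_id: str = "",
    variant: str = "",
) -> RnDensityEstimate:
    """Density = mean lambda / median MCP home-range area (individuals/km^2).

    The estimate is withheld (density None) when the bootstrap goodness of
    fit rejects the model at the 5% level.
    """
    if not fit.converged:
        raise ValueError("density requires a converged fit")
    if profile.home_range_area is None or profile.home_range_area <= 0:
        raise ValueError(f"{profile.name}: home_range_area missing")
    gof_pass = gof.p_value > 0.05
    density = fit.mean_lambda / profile.home_range_area if gof_pass else None
    return RnDensityEstimate(
        species=profile.name, period_id=period_id, variant=variant,
        mean_lambda=fit.mean_lambda, home_range_area=profile.home_range_area,
        density=density, gof_pass=gof_pass,
    )
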