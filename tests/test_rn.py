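import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import poisson

from echodens.histories import DetectionHistory
from echodens.rn import (
    DetectionDesign,
    _log_count_prob,
    _nll_factory,
    fit_rn,
    mb_gof,
    prune_correlated,
    rank_site_covariates,
    rn_density,
    rn_detection_prob,
    select_detection_model,
    site_marginal_likelihood,
)
from echodens.simulate import simulate_rn


def brute_force_marginal(y, r, lam, K=200):
    """Independent oracle: plain-python enumeration over the latent N."""
    total = 0.0
    for n in range(K + 1):
        prod = 1.0
        for yj, rj in zip(y, r):
            if math.isnan(yj):
                continue
            p = 1.0 - (1.0 - rj) ** n
            prod *= p if yj == 1 else (1.0 - p)
        total += poisson.pmf(n, lam) * prod
    return total


class TestDetectionProb:
    def test_identities(self):
        assert rn_detection_prob(0.7, 0) == 0.0
        assert rn_detection_prob(0.7, 1) == pytest.approx(0.7)

    def test_hand_arithmetic(self):
        assert rn_detection_prob(0.2, 3) == pytest.approx(0.488)

    def test_monotone_in_both_arguments(self):
        assert rn_detection_prob(0.2, 4) >= rn_detection_prob(0.2, 3)
        assert rn_detection_prob(0.3, 3) >= rn_detection_prob(0.2, 3)

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            rn_detection_prob(1.2, 1)
        with pytest.raises(ValueError):
            rn_detection_prob(0.2, -1)


class TestSiteMarginalLikelihood:
    def test_worked_value(self):
        assert site_marginal_likelihood([1, 0], [0.5, 0.5], 1.0) == pytest.approx(
            0.13417, abs=5e-5)

    def test_matches_brute_force_on_random_cases(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            j = rng.integers(1, 5)
            y = rng.integers(0, 2, j).astype(float)
            if rng.random() < 0.3 and j > 1:
                y[rng.integers(j)] = np.nan
            r = rng.uniform(0.05, 0.95, j)
            lam = rng.uniform(0.1, 8.0)
            mine = site_marginal_likelihood(y, r, lam)
            ref = brute_force_marginal(y, r, lam)
            assert mine == pytest.approx(ref, abs=1e-10)

    def test_small_lambda_all_zero_history_tends_to_one(self):
        assert site_marginal_likelihood([0, 0, 0], [0.5] * 3, 1e-9) == pytest.approx(
            1.0, abs=1e-6)

    def test_insufficient_k_is_raised_with_warning(self):
        with pytest.warns(UserWarning, match="tail mass"):
            v = site_marginal_likelihood([1, 0], [0.5, 0.5], 30.0, K=35)
        assert v == pytest.approx(brute_force_marginal([1, 0], [0.5, 0.5], 30.0, K=300),
                                  rel=1e-8)

    def test_count_probabilities_normalize(self):
        # sum over all binary histories of length J must be 1 per site
        logf = _log_count_prob(np.array([logit(0.3)]), np.array([np.log(2.0)]), 6)[0]
        total = sum(math.comb(6, k) * np.exp(logf[k]) for k in range(7))
        assert total == pytest.approx(1.0, abs=1e-9)


class TestDetectionDesign:
    def test_polynomials_require_lower_orders(self):
        with pytest.raises(ValueError, match="slot2 requires slot"):
            DetectionDesign(("intercept", "slot2"))

    def test_intercept_mandatory(self):
        with pytest.raises(ValueError, match="intercept"):
            DetectionDesign(("temp",))

    def test_from_orders_round_trip(self):
        d = DetectionDesign.from_orders(temp=2, slot=4, device=True)
        assert d.terms == ("intercept", "temp", "temp2",
                           "slot", "slot2", "slot3", "slot4", "device")


class TestFitRN:
    def test_parameter_recovery(self, rn_truth):
        fit = fit_rn(rn_truth.history, seed=0)
        lam_hat = float(np.exp(fit.ab_coefs[0]))
        assert abs(lam_hat - 2.0) / 2.0 < 0.10
        assert fit.converged
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)

    def test_general_and_fast_likelihood_paths_agree(self, rn_truth):
        y = rn_truth.history.y[:40]
        xd = np.ones((40, y.shape[1], 1))
        xa = np.ones((40, 1))
        theta = np.array([logit(0.3), np.log(2.0)])
        fast = _nll_factory(y, xd, xa)(theta)
        y_gen = y.copy()
        y_gen[0, 0] = np.nan  # missing value forces the general path
        general_nll = _nll_factory(y_gen, xd, xa)(theta)
        manual = -sum(np.log(site_marginal_likelihood(
            row, np.full(y.shape[1], 0.3), 2.0)) for row in y_gen)
        assert general_nll == pytest.approx(manual, rel=1e-9)
        manual_fast = -sum(np.log(site_marginal_likelihood(
            row, np.full(y.shape[1], 0.3), 2.0)) for row in y)
        assert fast == pytest.approx(manual_fast, rel=1e-9)

    def test_tiny_dataset_matches_grid_search(self):
        y = np.array([[1.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        hist = _tiny_history(y)
        fit = fit_rn(hist, seed=1)
        grid = np.arange(-3.0, 3.01, 0.05)
        best, best_ll = None, -np.inf
        for ed, ea in itertools.product(grid, grid):
            r = expit(ed)
            ll = sum(np.log(brute_force_marginal(row, [r, r], np.exp(ea), K=80))
                     for row in y)
            if ll > best_ll:
                best, best_ll = (ed, ea), ll
        assert fit.loglik >= best_ll - 1e-6
        assert abs(fit.det_coefs[0] - best[0]) <= 0.06
        assert abs(fit.ab_coefs[0] - best[1]) <= 0.06

    def test_all_zero_history_warns_boundary(self):
        hist = _tiny_history(np.zeros((3, 2)))
        with pytest.warns(UserWarning, match="all-zero"):
            fit = fit_rn(hist, seed=0)
        assert fit.mean_lambda < 0.05

    def test_centering_invariance_of_abundance_covariate(self):
        truth = simulate_rn(120, 8, {"(Intercept)": np.log(2.0), "cov": 0.5},
                            {"intercept": logit(0.3)}, seed=4)
        fit0 = fit_rn(truth.history, abundance_covariates=["cov"], seed=2)
        shifted = truth.history
        shifted.site_cov["cov"] = shifted.site_cov["cov"] + 5.0
        fit1 = fit_rn(shifted, abundance_covariates=["cov"], seed=2)
        assert fit1.loglik == pytest.approx(fit0.loglik, abs=1e-4)
        np.testing.assert_allclose(fit1.lambda_site, fit0.lambda_site, rtol=1e-3)


def _tiny_history(y):
    n, j = y.shape
    return DetectionHistory(
        sites=[f"s{i}" for i in range(n)],
        occasions=[(pd.Timestamp("2016-06-20"), k + 1) for k in range(j)],
        y=y, slot_index=np.arange(1, j + 1), n_sessions=j,
        occ_cov={"temp": np.zeros_like(y), "temp_missing": np.zeros_like(y),
                 "hum": np.zeros_like(y), "hum_missing": np.zeros_like(y)},
        site_cov=pd.DataFrame(index=[f"s{i}" for i in range(n)]),
        device=np.array(["d0"] * n),
    )


class TestModelSelection:
    CANDS = [DetectionDesign.from_orders(),
             DetectionDesign.from_orders(temp=1),
             DetectionDesign.from_orders(temp=2),
             DetectionDesign.from_orders(slot=1)]

    def test_null_data_keeps_intercept_competitive(self):
        truth = simulate_rn(150, 10, {"(Intercept)": np.log(2.0)},
                            {"intercept": logit(0.3)}, seed=9)
        table = select_detection_model(truth.history, self.CANDS, seed=0)
        row = table[table["label"] == "intercept"]
        assert row["delta_aic"].iloc[0] <= 2 * 2  # within 2*k of the top

    def test_strong_temperature_effect_recovered(self):
        truth = simulate_rn(150, 10, {"(Intercept)": np.log(2.0)},
                            {"intercept": logit(0.3), "temp": 1.2}, seed=10)
        table = select_detection_model(truth.history, self.CANDS, seed=0)
        assert "temp" in table.iloc[0]["label"]

    def test_single_candidate_trivially_wins(self, rn_truth):
        table = select_detection_model(rn_truth.history, [DetectionDesign()], seed=0)
        assert len(table) == 1 and table.iloc[0]["label"] == "intercept"


class TestCovariateSelection:
    def test_planted_signal_ranked_first(self):
        rng = np.random.default_rng(0)
        resp = rng.poisson(3.0, 150).astype(float)
        cov = pd.DataFrame({
            "signal": resp + rng.normal(0, 0.3, 150),
            "noise1": rng.normal(size=150),
            "noise2": rng.normal(size=150),
        })
        ranked = rank_site_covariates(cov, resp, seed=1)
        assert ranked["covariate"].iloc[0] == "signal"

    def test_constant_response_yields_empty_ranking(self):
        cov = pd.DataFrame({"a": np.arange(10.0)})
        with pytest.warns(UserWarning, match="constant response"):
            ranked = rank_site_covariates(cov, np.ones(10))
        assert len(ranked) == 0

    def test_mtry_default_is_18(self):
        import inspect

        assert inspect.signature(rank_site_covariates).parameters["mtry"].default == 18

    def test_prune_duplicate_keeps_higher_ranked(self):
        cov = pd.DataFrame({"a": np.arange(10.0), "b": np.arange(10.0)})
        assert prune_correlated(["a", "b"], cov) == ["a"]

    def test_prune_uncorrelated_unchanged(self):
        rng = np.random.default_rng(1)
        cov = pd.DataFrame(rng.normal(size=(200, 3)), columns=["a", "b", "c"])
        assert prune_correlated(["a", "b", "c"], cov) == ["a", "b", "c"]

    def test_prune_chain_hand_traced(self):
        # corr(A,B) ~ 0.7, corr(B,C) ~ 0.7, corr(A,C) ~ 0.1 -> keep {A, C}
        rng = np.random.default_rng(2)
        n = 4000
        a = rng.normal(size=n)
        c = 0.1 * a + np.sqrt(1 - 0.01) * rng.normal(size=n)
        b = 0.65 * a + 0.65 * c + 0.38 * rng.normal(size=n)
        cov = pd.DataFrame({"A": a, "B": b, "C": c})
        assert abs(np.corrcoef(a, b)[0, 1]) > 0.6
        assert abs(np.corrcoef(b, c)[0, 1]) > 0.6
        assert abs(np.corrcoef(a, c)[0, 1]) < 0.6
        assert prune_correlated(["A", "B", "C"], cov) == ["A", "C"]


class TestGof:
    def test_c_hat_is_observed_over_bootstrap_mean(self, rn_truth):
        fit = fit_rn(rn_truth.history, n_restarts=2, seed=0)
        g = mb_gof(fit, n_boot=60, seed=5)
        assert g.c_hat == pytest.approx(g.chi2_observed / g.chi2_bootstrap.mean())
        assert 0.0 <= g.p_value <= 1.0
        assert g.n_boot == len(g.chi2_bootstrap)

    def test_general_path_runs_with_missing_data_and_covariates(self):
        truth = simulate_rn(40, 4, {"(Intercept)": np.log(1.5)},
                            {"intercept": logit(0.4), "temp": 0.3}, seed=6)
        truth.history.y[0, 0] = np.nan
        fit = fit_rn(truth.history, DetectionDesign.from_orders(temp=1),
                     n_restarts=2, seed=0)
        g = mb_gof(fit, n_boot=30, seed=7)
        assert g.n_boot + g.n_failed == 30
        assert g.chi2_observed > 0


class TestDensity:
    def _gof(self, p):
        from echodens.rn import GofResult

        return GofResult(1.0, np.ones(10), p, 1.0, 10)

    def test_density_is_lambda_over_area(self, rn_truth, pip_profile):
        fit = fit_rn(rn_truth.history, n_restarts=2, seed=0)
        prof = pip_profile
        est = rn_density(fit, prof, self._gof(0.5), "P1", "strict")
        assert est.density == pytest.approx(fit.mean_lambda / prof.home_range_area)
        # hand arithmetic of the published convention
        assert 1.5 / 0.85 == pytest.approx(1.76, abs=0.005)

    def test_withheld_when_gof_rejects(self, rn_truth, pip_profile):
        fit = fit_rn(rn_truth.history, n_restarts=2, seed=0)
        est = rn_density(fit, pip_profile, self._gof(0.01))
        assert est.density is None and not est.gof_pass
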