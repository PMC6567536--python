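"""Estimators: standardization identities, likelihood oracles,
missing-data treatments."""

import math

import numpy as np
import pytest
from scipy import integrate, optimize, stats

from mnarsim import (
    MISettings,
    MissingnessScenario,
    OrdinalSpec,
    PopulationParams,
    apply_missingness,
    fit_linear_cc,
    fit_probit_cc,
    fit_probit_fiml,
    fit_probit_mi,
    fully_observed,
    generate_complete_sample,
    ordinalize,
    standardize_probit,
)
from mnarsim.estimators import fiml_loglike


def _ordinal_obs(params=None, n=1000, seed=0, scen=None, miss_seed=1, n_cat=4):
    params = params or PopulationParams()
    s = generate_complete_sample(params, n, seed=seed)
    obs = apply_missingness(s, scen, miss_seed) if scen else fully_observed(s)
    codes = ordinalize(obs.y_obs, OrdinalSpec(n_cat), sd=params.sd_y)
    return obs.with_outcome(codes)


class TestStandardization:
    def test_null_coefficients(self):
        bs, factors, sd_u = standardize_probit(np.zeros(2), np.eye(2) * 1.15)
        assert sd_u == 1.0
        np.testing.assert_array_equal(bs, np.zeros(2))

    def test_single_predictor_formula(self):
        # b = 1, V(x) = 1.15: SD(u*) = sqrt(2.15), bs = sqrt(1.15/2.15)
        bs, _, sd_u = standardize_probit(np.array([1.0]), np.array([[1.15]]))
        assert sd_u == pytest.approx(math.sqrt(2.15), abs=1e-4)
        assert bs[0] == pytest.approx(0.7313, abs=1e-4)

    def test_generating_model_maps_to_population_values(self):
        # standardizing the true raw coefficients with the theoretical
        # predictor covariance returns the population values
        bs, _, sd_u = standardize_probit(
            np.array([0.2, 0.3]), np.eye(2) * 1.15
        )
        assert sd_u == pytest.approx(math.sqrt(1.1495), abs=1e-9)
        np.testing.assert_allclose(bs, [0.2, 0.3], atol=1e-3)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            standardize_probit(np.array([0.1]), np.eye(2))


def _oracle_ordered_probit_llf(y_codes, X):
    """Independent ordered-probit maximum log-likelihood: direct
    threshold parameterization, two optimizers, multiple starts."""
    cats = np.unique(y_codes)
    y_idx = np.searchsorted(cats, y_codes)
    n_thresh = len(cats) - 1

    def negll(theta):
        b = theta[:2]
        cuts = np.sort(theta[2:])
        padded = np.concatenate(([-np.inf], cuts, [np.inf]))
        mu = X @ b
        p = stats.norm.cdf(padded[y_idx + 1] - mu) - stats.norm.cdf(
            padded[y_idx] - mu
        )
        return -np.sum(np.log(np.clip(p, 1e-300, None)))

    base_cuts = stats.norm.ppf(
        np.cumsum(np.bincount(y_idx))[:-1] / len(y_idx)
    )
    best = np.inf
    for b0 in (np.zeros(2), np.array([0.5, 0.5])):
        start = np.concatenate([b0, base_cuts])
        for method in ("Nelder-Mead", "BFGS"):
            res = optimize.minimize(
                negll, start, method=method,
                options={"maxiter": 5000, "xatol": 1e-10, "fatol": 1e-12}
                if method == "Nelder-Mead" else {"gtol": 1e-10},
            )
            best = min(best, res.fun)
    return -best


class TestOrderedProbitCC:
    def test_likelihood_optimum_matches_independent_oracle(self):
        obs = _ordinal_obs(
            n=700, seed=21,
            scen=MissingnessScenario(0.1, 0.1, 0.70), miss_seed=22,
        )
        fit = fit_probit_cc(obs)
        mask = obs.observed
        X = np.column_stack([obs.x1[mask], obs.x2[mask]])
        oracle = _oracle_ordered_probit_llf(obs.y_obs[mask], X)
        assert fit.llf == pytest.approx(oracle, abs=1e-4)

    def test_thresholds_strictly_increasing(self):
        obs = _ordinal_obs(n=800, seed=30, n_cat=5)
        fit = fit_probit_cc(obs)
        assert fit.converged
        assert np.all(np.diff(fit.info["thresholds"]) > 0)

    def test_wald_ci_construction(self):
        obs = _ordinal_obs(n=500, seed=31)
        f = fit_probit_cc(obs)
        lo, hi = f.ci1
        assert lo == pytest.approx(f.bs1 - 1.96 * f.se1)
        assert hi == pytest.approx(f.bs1 + 1.96 * f.se1)

    def test_single_category_rejected(self):
        obs = _ordinal_obs(n=100, seed=32)
        flat = obs.with_outcome(np.ones(obs.n))
        with pytest.raises(ValueError):
            fit_probit_cc(flat)

    def test_null_population_estimates_near_zero(self):
        p = PopulationParams(b_pred1=0.0, b_pred2=0.0)
        ests = []
        for r in range(30):
            obs = _ordinal_obs(params=p, n=1000, seed=400 + r)
            f = fit_probit_cc(obs)
            ests.append([f.bs1, f.bs2])
        np.testing.assert_allclose(np.mean(ests, axis=0), [0, 0], atol=0.02)


class TestFIML:
    def test_joint_loglike_matches_quadrature_oracle(self):
        obs = _ordinal_obs(
            n=50, seed=41, scen=MissingnessScenario(0.1, 0.1, 0.70),
            miss_seed=42,
        )
        theta = np.array([
            0.2, 0.3,                  # b
            -1.0, math.log(1.0), math.log(1.0),  # cut1, log-diffs
            0.0, 0.1, 0.0,             # aux regression a0, a1, a2
            math.log(1.05),            # log sigma3
            math.atanh(0.2),           # atanh r
        ])
        b = theta[:2]
        cuts = np.array([-1.0, 0.0, 1.0])
        a = theta[5:8]
        sig3 = math.exp(theta[8])
        r = math.tanh(theta[9])
        cov = np.array([[1.0, r * sig3], [r * sig3, sig3**2]])
        mvn = stats.multivariate_normal(mean=[0, 0], cov=cov)
        padded = np.concatenate(([-np.inf], cuts, [np.inf]))

        ll = 0.0
        for i in range(obs.n):
            mu_y = b[0] * obs.x1[i] + b[1] * obs.x2[i]
            mu_3 = a[0] + a[1] * obs.x1[i] + a[2] * obs.x2[i]
            if obs.m[i] == 1:
                ll += stats.norm.logpdf(obs.x3[i], mu_3, sig3)
            else:
                k = int(obs.y_obs[i]) - 1
                lo = max(padded[k] - mu_y, -40)
                hi = min(padded[k + 1] - mu_y, 40)
                val, _ = integrate.quad(
                    lambda t: mvn.pdf([t, obs.x3[i] - mu_3]), lo, hi
                )
                ll += math.log(val)
        assert fiml_loglike(obs, theta) == pytest.approx(ll, abs=1e-3)

    def test_uninformative_auxiliary_reduces_to_cc(self):
        # x3 independent of everything: FIML estimates match CC
        p = PopulationParams(rho_x3=0.0)
        obs = _ordinal_obs(
            params=p, n=1000, seed=43,
            scen=MissingnessScenario(0.0, 0.0, 0.70), miss_seed=44,
        )
        cc = fit_probit_cc(obs)
        fi = fit_probit_fiml(obs)
        assert fi.converged
        assert fi.bs1 == pytest.approx(cc.bs1, abs=0.02)
        assert fi.bs2 == pytest.approx(cc.bs2, abs=0.02)

    def test_agrees_with_cc_without_missingness(self):
        obs = _ordinal_obs(n=800, seed=45)
        cc = fit_probit_cc(obs)
        fi = fit_probit_fiml(obs)
        assert fi.bs1 == pytest.approx(cc.bs1, abs=0.02)
        assert fi.bs2 == pytest.approx(cc.bs2, abs=0.02)


class TestMI:
    def test_no_missing_values_returns_cc_exactly(self):
        obs = _ordinal_obs(n=600, seed=51)
        cc = fit_probit_cc(obs)
        mi = fit_probit_mi(obs, MISettings(m_imputations=5), seed=52)
        assert mi.method == "MI"
        assert (mi.bs1, mi.bs2, mi.se1, mi.se2) == (
            cc.bs1, cc.bs2, cc.se1, cc.se2
        )

    def test_deterministic_given_seed(self):
        obs = _ordinal_obs(
            n=600, seed=53, scen=MissingnessScenario(0.1, 0.1, 0.70),
            miss_seed=54,
        )
        a = fit_probit_mi(obs, MISettings(m_imputations=5), seed=99)
        b = fit_probit_mi(obs, MISettings(m_imputations=5), seed=99)
        assert (a.bs1, a.se1) == (b.bs1, b.se1)
        c = fit_probit_mi(obs, MISettings(m_imputations=5), seed=100)
        assert a.bs1 != c.bs1

    def test_imputed_values_are_observed_donor_codes(self):
        from mnarsim.estimators import _pmm_impute

        obs = _ordinal_obs(
            n=400, seed=55, scen=MissingnessScenario(0.3, 0.3, 0.50),
            miss_seed=56,
        )
        miss = ~obs.observed
        X = np.column_stack([np.ones(obs.n), obs.x1, obs.x2, obs.x3])
        rng = np.random.default_rng(57)
        completed = _pmm_impute(obs.y_obs, X, miss, rng, donors=5)
        observed_codes = set(np.unique(obs.y_obs[~miss]))
        assert set(np.unique(completed[miss])) <= observed_codes
        np.testing.assert_array_equal(completed[~miss], obs.y_obs[~miss])

    def test_mcar_pooled_estimates_near_truth(self):
        ests = []
        for r in range(30):
            obs = _ordinal_obs(
                n=1000, seed=600 + r,
                scen=MissingnessScenario(0.0, 0.0, 0.70), miss_seed=700 + r,
            )
            f = fit_probit_mi(obs, MISettings(m_imputations=5), seed=800 + r)
            ests.append([f.bs1, f.bs2])
        np.testing.assert_allclose(
            np.mean(ests, axis=0), [0.2, 0.3], atol=0.02
        )

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            MISettings(m_imputations=1)
        with pytest.raises(ValueError):
            MISettings(donor_pool=0)


class TestLinearCC:
    def test_closed_form_on_orthogonal_design(self):
        # orthogonal 5-row design: slope_j = sum(x_j*y)/sum(x_j^2),
        # so b1 = 10/10 = 1 and b2 = 0/14 = 0 by hand
        from mnarsim.missingness import ObservedSample
        from mnarsim.population import CompleteSample

        x1 = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        x2 = np.array([2.0, -1.0, -2.0, -1.0, 2.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        s = CompleteSample(x1=x1, x2=x2, x3=np.zeros(5) + 0.1, y_cont=y)
        obs = ObservedSample(
            sample=s, m=np.zeros(5, dtype=int), y_obs=y.copy(),
            scenario=MissingnessScenario(0, 0, 0.5),
        )
        f = fit_linear_cc(obs)
        assert f.bs1 == pytest.approx(1.0, abs=1e-10)
        assert f.bs2 == pytest.approx(0.0, abs=1e-10)

    def test_recovers_population_coefficients(self):
        ests = []
        for r in range(50):
            p = PopulationParams()
            s = generate_complete_sample(p, 1000, seed=900 + r)
            f = fit_linear_cc(fully_observed(s))
            ests.append([f.bs1, f.bs2])
        np.testing.assert_allclose(
            np.mean(ests, axis=0), [0.2, 0.3], atol=0.01
        )

    def test_extreme_truncation_biases_more_than_underrepresentation(self):
        # the continuous-outcome follow-up contrast at 50% response
        means = {}
        for removed in (False, True):
            scen = MissingnessScenario(
                0.3, 0.3, 0.50, extremes_removed=removed
            )
            est = []
            for r in range(50):
                s = generate_complete_sample(PopulationParams(), 1000, 950 + r)
                obs = apply_missingness(s, scen, seed=990 + r)
                est.append(fit_linear_cc(obs).bs1)
            means[removed] = np.mean(est)
        assert means[True] < means[False] < 0.2


def test_all_estimators_agree_on_complete_data():
    obs = _ordinal_obs(n=800, seed=61)
    cc = fit_probit_cc(obs)
    mi = fit_probit_mi(obs, MISettings(m_imputations=5), seed=62)
    fi = fit_probit_fiml(obs)
    assert mi.bs1 == cc.bs1 and mi.bs2 == cc.bs2
    assert fi.bs1 == pytest.approx(cc.bs1, abs=0.02)
    assert fi.bs2 == pytest.approx(cc.bs2, abs=0.02)
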