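"""Estimators of the risk-factor/outcome association under missing data.

All estimators regress the observed (usually ordinal) health outcome
on the two risk factors x1 and x2 and report coefficients on the
latent-response metric, so the unbiased value equals the population
coefficient (0.20 for x1, 0.30 for x2 under the default population).

Three missing-data treatments are provided:

``CC``
    complete-case ordered probit (latent residual variance fixed to 1);
``FIML``
    full-information maximum likelihood over all rows for a joint model
    of the latent response and the auxiliary covariate x3: the latent
    outcome is probit-regressed on x1 and x2, x3 is linearly regressed
    on x1 and x2, and their residuals correlate.  Rows with a missing
    outcome contribute the marginal likelihood of x3, which is how the
    auxiliary variable carries information about the missing outcomes;
``MI``
    multiple imputation of the ordinal outcome by predictive mean
    matching (Bayesian parameter draw, nearest-predicted-mean donors),
    ordered probit per completed data set, Rubin's rules pooling on the
    standardized metric.

Raw probit coefficients are standardized as

    bs = b * SD(x) / SD(u*),   SD(u*) = sqrt(Var(Xb) + 1),

the rescaling onto the underlying continuous latent response.  SEs are
multiplied by the same per-coefficient factor (delta method ignoring
the sampling variability of the scale factor) and 95% CIs are Wald,
bs +/- 1.96*SE.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.numdiff import approx_hess1

from .missingness import ObservedSample

__all__ = [
    "FitResult",
    "MISettings",
    "standardize_probit",
    "fit_probit_cc",
    "fit_probit_fiml",
    "fit_probit_mi",
    "fit_linear_cc",
    "fit",
]

Z95 = 1.96  # Wald critical value used throughout


@dataclass(frozen=True)
class FitResult:
    """Standardized estimates for x1 and x2 from one fitted sample."""

    method: str
    bs1: float
    bs2: float
    se1: float
    se2: float
    converged: bool
    n_used: int
    b_raw: tuple[float, float] | None = None
    llf: float | None = None
    info: dict = field(default_factory=dict)

    @property
    def ci1(self) -> tuple[float, float]:
        return (self.bs1 - Z95 * self.se1, self.bs1 + Z95 * self.se1)

    @property
    def ci2(self) -> tuple[float, float]:
        return (self.bs2 - Z95 * self.se2, self.bs2 + Z95 * self.se2)

    def ci(self, predictor: int) -> tuple[float, float]:
        if predictor == 1:
            return self.ci1
        if predictor == 2:
            return self.ci2
        raise ValueError(f"predictor must be 1 or 2, got {predictor}")

    def estimate(self, predictor: int) -> float:
        return {1: self.bs1, 2: self.bs2}[predictor]

    def se(self, predictor: int) -> float:
        return {1: self.se1, 2: self.se2}[predictor]


@dataclass(frozen=True)
class MISettings:
    """Multiple-imputation settings (study default: 50 imputations)."""

    m_imputations: int = 50
    donor_pool: int = 5
    max_dropped_fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.m_imputations < 2:
            raise ValueError("m_imputations must be at least 2")
        if self.donor_pool < 1:
            raise ValueError("donor_pool must be at least 1")


def standardize_probit(
    b_raw: np.ndarray, predictor_covariance: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Rescale raw probit coefficients to the latent-response metric.

    Parameters
    ----------
    b_raw
        Raw coefficients of the analysis predictors.
    predictor_covariance
        Covariance matrix of those predictors (sample covariance of the
        rows entering the fit, or the theoretical matrix).

    Returns
    -------
    bs, factors, sd_u
        Standardized coefficients, the per-coefficient scale factors
        SD(x_j)/SD(u*) (apply them to SEs), and SD(u*) itself, where
        Var(u*) = b' Cov(x) b + 1 uses all predictors jointly.
    """
    b = np.asarray(b_raw, dtype=float)
    S = np.asarray(predictor_covariance, dtype=float)
    if S.shape != (len(b), len(b)):
        raise ValueError("predictor_covariance shape does not match b_raw")
    var_u = float(b @ S @ b) + 1.0
    sd_u = math.sqrt(var_u)
    sd_x = np.sqrt(np.diag(S))
    factors = sd_x / sd_u
    return b * factors, factors, sd_u


def _sample_cov(X: np.ndarray) -> np.ndarray:
    return np.cov(X, rowvar=False, ddof=1)


def _ordered_probit_raw(y_codes: np.ndarray, X: np.ndarray):
    """Fit an ordered probit (latent residual variance 1) and return
    (b, se_b, converged, llf, result)."""
    y_ser = pd.Series(pd.Categorical(y_codes, ordered=True))
    n_cat = len(y_ser.cat.categories)
    if n_cat < 2:
        raise ValueError("need at least 2 observed outcome categories")
    exog = pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(X.shape[1])])
    model = OrderedModel(y_ser, exog, distr="probit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="lbfgs", disp=0, pgtol=1e-8, maxiter=500)
        converged = bool(res.mle_retvals.get("converged", False))
        if not converged:
            # second start: BFGS from the L-BFGS solution
            res = model.fit(
                method="bfgs", disp=0, gtol=1e-8, maxiter=500,
                start_params=res.params,
            )
            converged = bool(res.mle_retvals.get("converged", False))
    k = X.shape[1]
    return (
        res.params.to_numpy()[:k],
        res.bse.to_numpy()[:k],
        converged,
        float(res.llf),
        res,
    )


def fit_probit_cc(obs: ObservedSample) -> FitResult:
    """Complete-case ordered probit of the ordinal outcome on x1, x2.

    Only responders (m = 0) enter the likelihood and the
    standardization moments.  An outcome category empty after listwise
    deletion simply contributes no threshold (it is collapsed into its
    neighbour); the number of categories actually used is recorded in
    ``info``.
    """
    mask = obs.observed
    y = obs.y_obs[mask]
    X = np.column_stack([obs.x1[mask], obs.x2[mask]])
    b, se_b, converged, llf, res = _ordered_probit_raw(y, X)
    S = _sample_cov(X)
    bs, factors, sd_u = standardize_probit(b, S)
    cuts = res.model.transform_threshold_params(res.params)[1:-1]
    return FitResult(
        method="CC",
        bs1=float(bs[0]), bs2=float(bs[1]),
        se1=float(se_b[0] * factors[0]), se2=float(se_b[1] * factors[1]),
        converged=converged,
        n_used=int(mask.sum()),
        b_raw=(float(b[0]), float(b[1])),
        llf=llf,
        info={
            "sd_u": sd_u,
            "n_categories_used": len(np.unique(y)),
            "thresholds": tuple(float(c) for c in cuts),
        },
    )


# ---------------------------------------------------------------------
# FIML with auxiliary variable
# ---------------------------------------------------------------------

_LOG_EPS = 1e-300


def _fiml_unpack(theta: np.ndarray, n_thresh: int):
    b = theta[:2]
    cuts = np.empty(n_thresh)
    cuts[0] = theta[2]
    if n_thresh > 1:
        cuts[1:] = theta[2] + np.cumsum(np.exp(theta[3:2 + n_thresh]))
    a = theta[2 + n_thresh:5 + n_thresh]
    sig3 = math.exp(theta[5 + n_thresh])
    r = math.tanh(theta[6 + n_thresh])
    return b, cuts, a, sig3, r


def _fiml_negll(
    theta: np.ndarray,
    x1: np.ndarray, x2: np.ndarray, x3: np.ndarray,
    y_idx: np.ndarray, obs_mask: np.ndarray, n_thresh: int,
) -> float:
    b, cuts, a, sig3, r = _fiml_unpack(theta, n_thresh)
    e3 = x3 - (a[0] + a[1] * x1 + a[2] * x2)
    ll = float(stats.norm.logpdf(e3, scale=sig3).sum())

    padded = np.concatenate(([-np.inf], cuts, [np.inf]))
    mu = (
        b[0] * x1[obs_mask] + b[1] * x2[obs_mask]
        + (r / sig3) * e3[obs_mask]
    )
    s = math.sqrt(max(1.0 - r * r, 1e-12))
    upper = (padded[y_idx + 1] - mu) / s
    lower = (padded[y_idx] - mu) / s
    p = stats.norm.cdf(upper) - stats.norm.cdf(lower)
    ll += float(np.log(np.clip(p, _LOG_EPS, None)).sum())
    return -ll


def fiml_loglike(obs: ObservedSample, theta: np.ndarray) -> float:
    """Joint log-likelihood of the FIML model at parameter vector
    ``theta`` = (b1, b2, cut1, log-diffs..., a0, a1, a2, log sig3,
    atanh r).  Exposed for validation against independent oracles."""
    mask = obs.observed
    y = obs.y_obs[mask]
    cats = np.unique(y)
    y_idx = np.searchsorted(cats, y)
    return -_fiml_negll(
        theta, obs.x1, obs.x2, obs.x3, y_idx, mask, len(cats) - 1
    )


def fit_probit_fiml(obs: ObservedSample) -> FitResult:
    """FIML ordered probit with x3 as auxiliary variable.

    Joint model: latent y* = b1*x1 + b2*x2 + e_y (Var(e_y) = 1, y*
    observed only through the ordinal categories), x3 = a0 + a1*x1 +
    a2*x2 + e_3, Corr(e_y, e_3) = r.  All n rows contribute: responders
    the joint (category, x3) likelihood, non-responders the marginal
    x3 likelihood.  b1, b2 keep their marginal (CC-comparable)
    interpretation; standardization uses the full-sample predictor
    covariance.
    """
    mask = obs.observed
    y = obs.y_obs[mask]
    cats = np.unique(y)
    if len(cats) < 2:
        raise ValueError("need at least 2 observed outcome categories")
    y_idx = np.searchsorted(cats, y)
    n_thresh = len(cats) - 1

    # starts: CC probit for (b, cuts); OLS of x3 on (x1, x2); r = 0
    cc_b, _, _, _, cc_res = _ordered_probit_raw(
        y, np.column_stack([obs.x1[mask], obs.x2[mask]])
    )
    cc_cuts = cc_res.model.transform_threshold_params(cc_res.params)[1:-1]
    Xa = np.column_stack([np.ones(obs.n), obs.x1, obs.x2])
    a_hat, *_ = np.linalg.lstsq(Xa, obs.x3, rcond=None)
    resid3 = obs.x3 - Xa @ a_hat
    sig3_hat = max(float(np.std(resid3, ddof=3)), 1e-6)

    theta0 = np.concatenate([
        cc_b,
        [cc_cuts[0]],
        np.log(np.clip(np.diff(cc_cuts), 1e-4, None)),
        a_hat,
        [math.log(sig3_hat)],
        [0.0],
    ])
    args = (obs.x1, obs.x2, obs.x3, y_idx, mask, n_thresh)
    best = None
    for start in (theta0, np.concatenate([theta0[:-1], [math.atanh(0.3)]])):
        res = optimize.minimize(
            _fiml_negll, start, args=args, method="BFGS",
            options={"gtol": 1e-8, "maxiter": 1000},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if best.success:
            break
    theta = best.x
    b, cuts, a, sig3, r = _fiml_unpack(theta, n_thresh)
    converged = bool(best.success) or float(np.abs(best.jac).max()) < 1e-4
    boundary = abs(r) > 0.999

    hess = approx_hess1(theta, _fiml_negll, args=args)
    try:
        cov = np.linalg.inv(hess)
        se_b = np.sqrt(np.clip(np.diag(cov)[:2], 0, None))
    except np.linalg.LinAlgError:
        se_b = np.full(2, np.nan)
        converged = False

    S = _sample_cov(np.column_stack([obs.x1, obs.x2]))
    bs, factors, sd_u = standardize_probit(b, S)
    return FitResult(
        method="FIML",
        bs1=float(bs[0]), bs2=float(bs[1]),
        se1=float(se_b[0] * factors[0]), se2=float(se_b[1] * factors[1]),
        converged=converged and not boundary,
        n_used=obs.n,
        b_raw=(float(b[0]), float(b[1])),
        llf=-float(best.fun),
        info={
            "sd_u": sd_u, "resid_corr": r, "sigma_x3": sig3,
            "aux_coefs": tuple(a), "boundary": boundary,
        },
    )


# ---------------------------------------------------------------------
# Multiple imputation by predictive mean matching
# ---------------------------------------------------------------------


def _pmm_impute(
    y: np.ndarray, X: np.ndarray, miss: np.ndarray,
    rng: np.random.Generator, donors: int,
) -> np.ndarray:
    """One predictive-mean-matching draw for the missing entries of y.

    Type-1 matching: regression parameters are drawn from their
    posterior; predicted means for missing rows use the drawn
    parameters, donors' predicted means use the least-squares fit, and
    each missing entry receives the observed value of a donor sampled
    from the ``donors`` closest predicted means.
    """
    obs = ~miss
    Xo, yo = X[obs], y[obs]
    n_obs, q = Xo.shape
    if n_obs <= q:
        raise ValueError("too few complete cases for the imputation model")
    XtX_inv = np.linalg.inv(Xo.T @ Xo)
    beta_hat = XtX_inv @ Xo.T @ yo
    resid = yo - Xo @ beta_hat
    df = n_obs - q
    sigma2_star = float(resid @ resid) / rng.chisquare(df)
    beta_star = beta_hat + np.linalg.cholesky(
        sigma2_star * XtX_inv
    ) @ rng.standard_normal(q)

    pred_obs = Xo @ beta_hat
    pred_mis = X[miss] @ beta_star
    k = min(donors, n_obs)
    dist = np.abs(pred_mis[:, None] - pred_obs[None, :])
    nearest = np.argpartition(dist, k - 1, axis=1)[:, :k]
    choice = rng.integers(0, k, size=len(pred_mis))
    donors_idx = nearest[np.arange(len(pred_mis)), choice]

    y_completed = y.copy()
    y_completed[miss] = yo[donors_idx]
    return y_completed


def fit_probit_mi(
    obs: ObservedSample,
    settings: MISettings = MISettings(),
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> FitResult:
    """Multiple imputation (PMM) then ordered probit, pooled by Rubin.

    The ordinal outcome codes are imputed with predictive mean matching
    on x1, x2 and x3 (x3 enters the imputation model only).  Each
    completed data set is analyzed by ordered probit on x1, x2 and
    standardized against the full-sample predictor covariance; Rubin's
    rules combine the standardized estimates (within + between
    variance).  With no missing values no imputation is performed and
    the complete-case result is returned.
    """
    miss = ~obs.observed
    if not miss.any():
        cc = fit_probit_cc(obs)
        return FitResult(
            method="MI", bs1=cc.bs1, bs2=cc.bs2, se1=cc.se1, se2=cc.se2,
            converged=cc.converged, n_used=cc.n_used, b_raw=cc.b_raw,
            llf=cc.llf, info={**cc.info, "m_imputations": 0},
        )
    rng = np.random.default_rng(seed)
    X_imp = np.column_stack([np.ones(obs.n), obs.x1, obs.x2, obs.x3])
    X_fit = np.column_stack([obs.x1, obs.x2])
    S_full = _sample_cov(X_fit)

    est, var = [], []
    n_failed = 0
    for _ in range(settings.m_imputations):
        y_comp = _pmm_impute(obs.y_obs, X_imp, miss, rng, settings.donor_pool)
        b, se_b, conv, _, _ = _ordered_probit_raw(y_comp, X_fit)
        if not conv:
            n_failed += 1
            continue
        bs, factors, _ = standardize_probit(b, S_full)
        est.append(bs)
        var.append((se_b * factors) ** 2)
    m_used = len(est)
    if m_used == 0:
        raise RuntimeError("no imputation run converged")
    est = np.asarray(est)
    var = np.asarray(var)
    qbar = est.mean(axis=0)
    if m_used > 1:
        between = est.var(axis=0, ddof=1)
    else:
        between = np.zeros(2)
    total = var.mean(axis=0) + (1.0 + 1.0 / m_used) * between
    se = np.sqrt(total)
    converged = n_failed <= settings.max_dropped_fraction * settings.m_imputations
    return FitResult(
        method="MI",
        bs1=float(qbar[0]), bs2=float(qbar[1]),
        se1=float(se[0]), se2=float(se[1]),
        converged=converged,
        n_used=obs.n,
        info={"m_imputations": m_used, "n_failed": n_failed},
    )


def fit_linear_cc(obs: ObservedSample) -> FitResult:
    """Complete-case OLS of the continuous outcome on x1, x2.

    Used in the follow-up design where the outcome is analyzed without
    ordinalization; coefficients are already on the population metric,
    so no standardization is applied.
    """
    mask = obs.observed
    y = obs.y_obs[mask]
    if np.isnan(y).any():
        raise ValueError("continuous outcome contains NaN among responders")
    X = np.column_stack([np.ones(mask.sum()), obs.x1[mask], obs.x2[mask]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    import statsmodels.api as sm

    res = sm.OLS(y, X).fit()
    b = res.params[1:]
    se = res.bse[1:]
    return FitResult(
        method="linear_CC",
        bs1=float(b[0]), bs2=float(b[1]),
        se1=float(se[0]), se2=float(se[1]),
        converged=True,
        n_used=int(mask.sum()),
        b_raw=(float(b[0]), float(b[1])),
        llf=float(res.llf),
    )


def fit(
    obs: ObservedSample,
    method: str,
    mi_settings: MISettings = MISettings(),
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> FitResult:
    """Dispatch on estimator name: CC, FIML, MI or linear_CC."""
    method = method.upper() if method.lower() != "linear_cc" else "linear_CC"
    if method == "CC":
        return fit_probit_cc(obs)
    if method == "FIML":
        return fit_probit_fiml(obs)
    if method == "MI":
        return fit_probit_mi(obs, mi_settings, seed)
    if method == "linear_CC":
        return fit_linear_cc(obs)
    raise ValueError(f"unknown estimator {method!r}")
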