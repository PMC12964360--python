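"""Count regressions and Tukey-adjusted treatment contrasts.

The seed-count models are log-link GLMs with a treatment-only fixed-effect
structure (reference level: autonomous, the alphabetical first). The
Poisson fit is a lack-of-fit diagnostic — its residual deviance against the
residual degrees of freedom reveals the overdispersion that motivates the
negative binomial model. The negative binomial GLM is fitted by joint
maximum likelihood: iteratively reweighted least squares for the
coefficients alternating with one-dimensional ML for the dispersion theta
(variance ``mu + mu**2 / theta``).

Pairwise contrasts on the linear-predictor scale use the studentized-range
law with infinite degrees of freedom (large-sample marginal-means
practice): ``p_tukey = P(Q_3 > |z| * sqrt(2))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

MAX_IRLS_ITER = 200
LL_TOL = 1e-8
PARAM_TOL = 1e-6
THETA_CAP = 1e6


@dataclass
class GlmFit:
    """A fitted log-link GLM for seed counts."""

    family: str  # "poisson" or "negbin"
    link: str
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    cov_params: np.ndarray
    theta: float | None
    log_likelihood: float
    residual_deviance: float
    residual_df: int
    n_obs: int
    factor: str = "treatment"
    levels: tuple[str, ...] = ()
    reference: str = ""
    warnings: list[str] = field(default_factory=list)

    @property
    def terms(self) -> list[str]:
        return list(self.coefficients)


@dataclass
class ContrastResult:
    """One pairwise contrast on the link scale."""

    pair: tuple[str, str]
    estimate: float
    se: float
    z: float
    p_unadjusted: float
    p_tukey: float


def _design(records: pd.DataFrame, factor: str) -> tuple[np.ndarray, list[str], tuple[str, ...], str]:
    levels = tuple(sorted(records[factor].unique()))
    reference = levels[0]  # single level ⇒ intercept-only model
    terms = ["Intercept"] + [f"{factor}[{lv}]" for lv in levels[1:]]
    X = np.ones((len(records), len(terms)))
    for j, lv in enumerate(levels[1:], start=1):
        X[:, j] = (records[factor] == lv).astype(float)
    return X, terms, levels, reference


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    # y * ln(y / mu) with the y = 0 term set to 0
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def _irls(y: np.ndarray, X: np.ndarray, weight_fn, max_iter: int = MAX_IRLS_ITER):
    """Log-link IRLS; ``weight_fn(mu)`` gives the working weights."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 0.1))
    for it in range(max_iter):
        eta = X @ beta
        mu = np.exp(eta)
        w = weight_fn(mu)
        z = eta + (y - mu) / mu  # working response for the log link
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        if np.max(np.abs(beta_new - beta)) < PARAM_TOL:
            return beta_new, it + 1
        beta = beta_new
    raise RuntimeError(
        f"IRLS did not converge in {max_iter} iterations; last beta = {beta}"
    )


def fit_poisson_glm(
    records: pd.DataFrame,
    response: str = "seeds_produced",
    factor: str = "treatment",
) -> GlmFit:
    """Maximum-likelihood Poisson GLM (log link) by IRLS.

    Intended as an overdispersion diagnostic: compare the residual deviance
    with the residual degrees of freedom.
    """
    y = records[response].to_numpy(dtype=float)
    X, terms, levels, ref = _design(records, factor)
    beta, _ = _irls(y, X, lambda mu: mu)
    mu = np.exp(X @ beta)
    cov = np.linalg.inv(X.T @ (X * mu[:, None]))
    ll = float(np.sum(stats.poisson.logpmf(y.astype(int), mu)))
    return GlmFit(
        family="poisson",
        link="log",
        coefficients=dict(zip(terms, beta)),
        standard_errors=dict(zip(terms, np.sqrt(np.diag(cov)))),
        cov_params=cov,
        theta=None,
        log_likelihood=ll,
        residual_deviance=_poisson_deviance(y, mu),
        residual_df=len(y) - len(terms),
        n_obs=len(y),
        factor=factor,
        levels=levels,
        reference=ref,
    )


def _negbin_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def _negbin_deviance(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    t2 = (y + theta) * np.log((y + theta) / (mu + theta))
    return float(2.0 * np.sum(t1 - t2))


def fit_negbin_glm(
    records: pd.DataFrame,
    response: str = "seeds_produced",
    factor: str = "treatment",
) -> GlmFit:
    """Joint-ML negative binomial GLM (log link, NB2 variance).

    Alternates IRLS for the coefficients with one-dimensional ML for theta
    until the log-likelihood changes by less than 1e-8. Standard errors come
    from the observed information of the joint (beta, log theta) likelihood.
    A diverging theta (no overdispersion) is capped at 1e6 with a
    Poisson-equivalence warning.
    """
    y = records[response].to_numpy(dtype=float)
    X, terms, levels, ref = _design(records, factor)

    theta = max(1.0, y.mean() ** 2 / max(y.var() - y.mean(), 1e-8))
    beta, _ = _irls(y, X, lambda mu: mu)  # Poisson start
    ll_old = -np.inf
    warns: list[str] = []
    for _ in range(100):
        beta, _ = _irls(y, X, lambda mu: mu / (1.0 + mu / theta))
        mu = np.exp(X @ beta)
        res = optimize.minimize_scalar(
            lambda lt: -_negbin_loglik(y, mu, np.exp(lt)),
            bounds=(np.log(1e-3), np.log(THETA_CAP)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        theta = float(np.exp(res.x))
        ll = _negbin_loglik(y, mu, theta)
        if abs(ll - ll_old) < LL_TOL:
            break
        ll_old = ll
    if theta > 1e5:
        # flat likelihood in theta: no overdispersion; report the Poisson fit
        theta = THETA_CAP
        beta, _ = _irls(y, X, lambda mu: mu)
        warns.append(
            "theta diverged (no overdispersion detected); capped at 1e6 — "
            "fit is Poisson-equivalent"
        )

    mu = np.exp(X @ beta)
    # observed information over (beta, log theta)
    params = np.append(beta, np.log(theta))

    def negll(p: np.ndarray) -> float:
        return -_negbin_loglik(y, np.exp(X @ p[:-1]), np.exp(p[-1]))

    H = _numeric_hessian(negll, params)
    try:
        cov_full = np.linalg.inv(H)
        se_full = np.sqrt(np.maximum(np.diag(cov_full), 0.0))
    except np.linalg.LinAlgError:
        cov_full = np.full((len(params),) * 2, np.nan)
        se_full = np.full(len(params), np.nan)
        warns.append("observed information singular; standard errors unavailable")
    cov = cov_full[: len(terms), : len(terms)]
    return GlmFit(
        family="negbin",
        link="log",
        coefficients=dict(zip(terms, beta)),
        standard_errors=dict(zip(terms, se_full[: len(terms)])),
        cov_params=cov,
        theta=theta,
        log_likelihood=_negbin_loglik(y, mu, theta),
        residual_deviance=_negbin_deviance(y, mu, theta),
        residual_df=len(y) - len(terms),
        n_obs=len(y),
        factor=factor,
        levels=levels,
        reference=ref,
        warnings=warns,
    )


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian."""
    k = len(x)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h * h)
    return H


def tukey_contrasts(fit, factor: str | None = None) -> list[ContrastResult]:
    """All pairwise level contrasts of ``fit``'s treatment factor.

    Estimates and SEs come from the coefficient covariance; the reference
    level's effect is zero. ``p_tukey`` is the studentized-range tail
    probability for ``|z| * sqrt(2)`` with k groups and infinite degrees of
    freedom; ``p_unadjusted`` is the two-sided normal tail.
    """
    levels = fit.levels
    if len(levels) < 2:
        raise ValueError("contrasts need a factor with >= 2 levels")
    fac = factor or fit.factor
    terms = fit.terms
    k = len(levels)

    def effect_vector(level: str) -> np.ndarray:
        v = np.zeros(len(terms))
        if level != fit.reference:
            v[terms.index(f"{fac}[{level}]")] = 1.0
        return v

    out = []
    for a, b in combinations(levels, 2):
        c = effect_vector(a) - effect_vector(b)
        est = float(c @ np.array([fit.coefficients[t] for t in terms]))
        se = float(np.sqrt(c @ fit.cov_params @ c))
        z = est / se if se > 0 else 0.0
        p_un = float(2.0 * stats.norm.sf(abs(z)))
        p_tk = float(stats.studentized_range.sf(abs(z) * np.sqrt(2.0), k, np.inf))
        out.append(
            ContrastResult(
                pair=(a, b), estimate=est, se=se, z=z, p_unadjusted=p_un, p_tukey=p_tk
            )
        )
    return out


def contrast_table(contrasts: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "level_a": [c.pair[0] for c in contrasts],
            "level_b": [c.pair[1] for c in contrasts],
            "estimate": [c.estimate for c in contrasts],
            "se": [c.se for c in contrasts],
            "z": [c.z for c in contrasts],
            "p_unadjusted": [c.p_unadjusted for c in contrasts],
            "p_tukey": [c.p_tukey for c in contrasts],
        }
    )
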