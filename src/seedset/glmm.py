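"""Binomial random-intercept GLMM for germination, fitted by maximum
marginal likelihood.

Each plant's inflorescences contribute binomial counts (seeds germinated
out of seeds produced) whose success log-odds share a plant-level random
intercept ``b ~ N(0, sigma^2)`` on top of treatment fixed effects. The
marginal likelihood integrates the random intercept out plant by plant:

    L = prod_plants  integral  prod_infl Binom(y | n, expit(X beta + b))
                               * phi(b; 0, sigma^2) db

The integral is evaluated by the Laplace approximation (default) or by
adaptive Gauss-Hermite quadrature with k nodes centred and scaled at each
plant's conditional mode; the likelihood is maximised over (beta, log
sigma). Given the data and method, the fit is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

SEPARATION_THRESHOLD = 15.0  # |beta| beyond this flags quasi-separation
_LOG_SIGMA_FLOOR = -8.0


@dataclass
class GlmmFit:
    """A fitted binomial GLMM with a plant random intercept."""

    family: str
    link: str
    fixed_effects: dict[str, float]
    fixed_se: dict[str, float]
    cov_params: np.ndarray
    re_sd: float
    log_likelihood: float
    method: str  # "laplace" or "agq(k)"
    n_groups: int
    n_obs: int
    factor: str = "treatment"
    levels: tuple[str, ...] = ()
    reference: str = ""
    warnings: list[str] = field(default_factory=list)

    # mirror GlmFit's contrast interface
    @property
    def coefficients(self) -> dict[str, float]:
        return self.fixed_effects

    @property
    def terms(self) -> list[str]:
        return list(self.fixed_effects)


def _expit(x):
    return special.expit(x)


def _conditional_modes(
    eta0: np.ndarray,
    y: np.ndarray,
    n: np.ndarray,
    group: np.ndarray,
    n_groups: int,
    sigma2: float,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton solve, vectorised over plants, for the mode of
    ``g(b) - b^2 / (2 sigma^2)`` where g is the conditional binomial
    log-likelihood. Returns the modes and the negative curvature H at the
    mode (H = -g''(b_hat) + 1/sigma^2)."""
    b = np.zeros(n_groups)
    for _ in range(max_iter):
        p = _expit(eta0 + b[group])
        grad = np.bincount(group, weights=y - n * p, minlength=n_groups) - b / sigma2
        info = np.bincount(group, weights=n * p * (1 - p), minlength=n_groups) + 1.0 / sigma2
        step = grad / info
        # damp oversized Newton steps for stability at extreme logits
        step = np.clip(step, -5.0, 5.0)
        b = b + step
        if np.max(np.abs(step)) < tol:
            break
    p = _expit(eta0 + b[group])
    H = np.bincount(group, weights=n * p * (1 - p), minlength=n_groups) + 1.0 / sigma2
    return b, H


def _binom_loglik_terms(
    eta: np.ndarray, y: np.ndarray, n: np.ndarray
) -> np.ndarray:
    """Per-record binomial log-pmf including the binomial coefficient."""
    const = special.gammaln(n + 1) - special.gammaln(y + 1) - special.gammaln(n - y + 1)
    return const + y * eta - n * np.logaddexp(0.0, eta)


def marginal_loglik(
    beta: np.ndarray,
    log_sigma: float,
    X: np.ndarray,
    y: np.ndarray,
    n: np.ndarray,
    group: np.ndarray,
    n_groups: int,
    method: str = "laplace",
    agq_nodes: int = 15,
) -> float:
    """Marginal log-likelihood with the random intercept integrated out."""
    sigma = float(np.exp(log_sigma))
    sigma2 = sigma * sigma
    eta0 = X @ beta

    if sigma < 1e-6:
        # degenerate random effect: plain binomial likelihood
        return float(np.sum(_binom_loglik_terms(eta0, y, n)))

    b_hat, H = _conditional_modes(eta0, y, n, group, n_groups, sigma2)
    g_hat = np.bincount(
        group, weights=_binom_loglik_terms(eta0 + b_hat[group], y, n), minlength=n_groups
    )

    if method == "laplace":
        # log integral ~= g(b_hat) - b_hat^2/(2 s2) - 0.5 log(s2 H)
        return float(np.sum(g_hat - b_hat**2 / (2 * sigma2) - 0.5 * np.log(sigma2 * H)))

    if method != "agq":
        raise ValueError(f"method must be 'laplace' or 'agq', got {method!r}")

    x_nodes, w_nodes = np.polynomial.hermite.hermgauss(agq_nodes)
    scale = 1.0 / np.sqrt(H)  # (n_groups,)
    # evaluation points: b_hat + sqrt(2) * scale * x_j
    B = b_hat[:, None] + np.sqrt(2.0) * scale[:, None] * x_nodes[None, :]
    # integrand log: g(b) - b^2/(2 s2) - 0.5 log(2 pi s2), per group/node
    log_int = np.empty((n_groups, agq_nodes))
    for j in range(agq_nodes):
        terms = _binom_loglik_terms(eta0 + B[group, j], y, n)
        log_int[:, j] = np.bincount(group, weights=terms, minlength=n_groups)
    log_int += -(B**2) / (2 * sigma2) - 0.5 * np.log(2 * np.pi * sigma2)
    # integral = sqrt(2) * scale * sum_j w_j exp(x_j^2) * integrand(b_j)
    log_w = np.log(w_nodes) + x_nodes**2
    ll = special.logsumexp(log_int + log_w[None, :], axis=1)
    ll += 0.5 * np.log(2.0) + np.log(scale)
    return float(np.sum(ll))


def fit_binomial_glmm(
    records: pd.DataFrame,
    successes: str = "seeds_germinated",
    trials: str = "seeds_produced",
    factor: str = "treatment",
    group_col: str = "plant_id",
    method: str = "laplace",
    agq_nodes: int = 15,
) -> GlmmFit:
    """Fit the germination GLMM.

    Parameters
    ----------
    records
        Retained inflorescence records. Plants whose trials are all zero
        carry no information and are excluded with a warning.
    method
        ``"laplace"`` (default) or ``"agq"`` (adaptive Gauss-Hermite with
        ``agq_nodes`` nodes).

    Notes
    -----
    Complete separation (e.g. a treatment with zero successes everywhere)
    has no finite ML solution; fits with any ``|beta| > 15`` are returned
    flagged rather than rejected.
    """
    df = records.copy()
    zero_plants = df.groupby(group_col)[trials].sum()
    dead = list(zero_plants.index[zero_plants == 0])
    warns: list[str] = []
    if dead:
        warns.append(f"{len(dead)} plant(s) with all-zero trials excluded: {dead}")
        warnings.warn(warns[-1], stacklevel=2)
        df = df[~df[group_col].isin(dead)]

    levels = tuple(sorted(df[factor].unique()))
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels")
    reference = levels[0]
    terms = ["Intercept"] + [f"{factor}[{lv}]" for lv in levels[1:]]
    X = np.ones((len(df), len(terms)))
    for j, lv in enumerate(levels[1:], start=1):
        X[:, j] = (df[factor] == lv).astype(float)

    y = df[successes].to_numpy(dtype=float)
    n = df[trials].to_numpy(dtype=float)
    groups_cat = pd.Categorical(df[group_col])
    group = groups_cat.codes.astype(int)
    n_groups = len(groups_cat.categories)

    # start: crude empirical logits per level
    beta0 = np.zeros(len(terms))
    pooled = (y.sum() + 0.5) / (n.sum() + 1.0)
    beta0[0] = np.log(pooled / (1 - pooled))
    x0 = np.append(beta0, np.log(0.5))

    def negll(params: np.ndarray) -> float:
        beta = params[:-1]
        log_sigma = max(params[-1], _LOG_SIGMA_FLOOR)
        return -marginal_loglik(
            beta, log_sigma, X, y, n, group, n_groups, method, agq_nodes
        )

    res = optimize.minimize(
        negll,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 4000, "maxfev": 6000},
    )
    # polish with BFGS from the simplex optimum
    res2 = optimize.minimize(negll, res.x, method="BFGS", options={"gtol": 1e-6})
    best = res2 if res2.fun <= res.fun else res
    params = best.x
    beta = params[:-1]
    sigma = float(np.exp(max(params[-1], _LOG_SIGMA_FLOOR)))

    if np.any(np.abs(beta) > SEPARATION_THRESHOLD):
        warns.append(
            "possible complete separation: a fixed effect exceeds 15 on the "
            "logit scale; estimates and SEs are unreliable"
        )

    from .regression import _numeric_hessian

    H = _numeric_hessian(negll, params, h=1e-4)
    try:
        cov_full = np.linalg.inv(H)
        se_full = np.sqrt(np.maximum(np.diag(cov_full), 0.0))
    except np.linalg.LinAlgError:
        cov_full = np.full((len(params),) * 2, np.nan)
        se_full = np.full(len(params), np.nan)
        warns.append("observed information singular; standard errors unavailable")

    method_label = "laplace" if method == "laplace" else f"agq({agq_nodes})"
    return GlmmFit(
        family="binomial",
        link="logit",
        fixed_effects=dict(zip(terms, beta)),
        fixed_se=dict(zip(terms, se_full[: len(terms)])),
        cov_params=cov_full[: len(terms), : len(terms)],
        re_sd=sigma,
        log_likelihood=float(-best.fun),
        method=method_label,
        n_groups=n_groups,
        n_obs=len(df),
        factor=factor,
        levels=levels,
        reference=reference,
        warnings=warns,
    )
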