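"""Single-species N-mixture model: Poisson abundance, binomial detection.

Latent abundance N at each sample unit (a point-year) is Poisson with a
log-linear covariate model; visit counts are Binomial(N, p) with a separate
detection probability per study year.  The marginal likelihood sums the
binomial likelihood over N up to a truncation bound K, and is maximized by
quasi-Newton search with standard errors from the inverse numerical Hessian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, gammaln, logsumexp
from statsmodels.tools.numdiff import approx_hess


class NonIdentifiableError(RuntimeError):
    """The likelihood carries no information about abundance vs detection."""


@dataclass
class NMixtureData:
    """Counts per sample unit and visit, with unit-level covariates."""

    counts: np.ndarray  # (n_units, n_visits) nonnegative ints
    covariates: np.ndarray  # (n_units, n_covs) standardized
    year_index: np.ndarray  # (n_units,) integer codes 0..n_years-1
    covariate_names: tuple[str, ...] = ()
    year_labels: tuple = ()

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        self.year_index = np.asarray(self.year_index, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not np.all(np.isfinite(self.covariates)):
            raise ValueError("covariates must be finite")
        if self.covariates.shape[0] != self.counts.shape[0]:
            raise ValueError("covariates/counts unit mismatch")
        if self.year_index.shape[0] != self.counts.shape[0]:
            raise ValueError("year_index/counts unit mismatch")

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_years(self) -> int:
        return int(self.year_index.max()) + 1 if self.n_units else 0

    @property
    def n_covs(self) -> int:
        return self.covariates.shape[1]


@dataclass
class NMixtureSpec:
    K: int | None = None  # default: max count + 100, auto-doubled to stability
    k_stability_tol: float = 1e-6


@dataclass
class NMixtureFit:
    abundance_coefs: np.ndarray  # intercept + slopes, log scale
    abundance_se: np.ndarray
    detection_coefs: np.ndarray  # per-year logits
    detection_se: np.ndarray
    loglik: float
    converged: bool
    non_identifiable: bool
    K: int
    covariate_names: tuple[str, ...] = ()
    year_labels: tuple = ()
    message: str = ""

    def to_frame(self) -> pd.DataFrame:
        names = list(self.covariate_names) or [
            f"x{i}" for i in range(1, len(self.abundance_coefs))
        ]
        terms = ["lambda_intercept"] + [f"lambda_{n}" for n in names]
        years = list(self.year_labels) or list(range(len(self.detection_coefs)))
        terms += [f"p_logit_year_{y}" for y in years]
        est = np.concatenate([self.abundance_coefs, self.detection_coefs])
        se = np.concatenate([self.abundance_se, self.detection_se])
        return pd.DataFrame(
            {
                "term": terms,
                "estimate": est,
                "se": se,
                "ci_low": est - 1.96 * se,
                "ci_high": est + 1.96 * se,
                "loglik": self.loglik,
                "K": self.K,
                "converged": self.converged,
            }
        )


def _split_params(params: np.ndarray, n_covs: int):
    beta = params[: n_covs + 1]
    alpha = params[n_covs + 1 :]
    return beta, alpha


def nmix_loglik(params: np.ndarray, data: NMixtureData, spec: NMixtureSpec) -> float:
    """Marginal log-likelihood: Poisson abundance summed out up to K.

    For each unit s:  log sum_{N=max_k y_sk}^{K} Pois(N; lambda_s)
    prod_k Binom(y_sk; N, p_year(s)), evaluated in log space.
    """
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)):
        return -np.inf
    K = spec.K if spec.K is not None else int(data.counts.max()) + 100
    max_y = data.counts.max(axis=1)  # (S,)
    if K < max_y.max():
        raise ValueError(f"K={K} below the maximum observed count {max_y.max()}")
    beta, alpha = _split_params(params, data.n_covs)
    if len(alpha) != data.n_years:
        raise ValueError("detection parameter count does not match years")
    eta = beta[0] + data.covariates @ beta[1:]  # (S,)
    log_lam = eta
    p = expit(alpha)[data.year_index]  # (S,)
    with np.errstate(divide="ignore"):
        logp = np.log(p)
        log1mp = np.log1p(-p)

    N = np.arange(K + 1)  # (K+1,)
    # Poisson log pmf over the N grid, per unit
    log_pois = N[None, :] * log_lam[:, None] - np.exp(log_lam)[:, None] - gammaln(
        N + 1
    )[None, :]
    # Binomial log pmf summed over visits: sum_k [C(N, y_sk) + y_sk log p + (N - y_sk) log(1-p)]
    y = data.counts  # (S, V)
    n_visits = y.shape[1]
    with np.errstate(invalid="ignore"):
        log_binom = (
            gammaln(N[None, None, :] + 1)
            - gammaln(y[:, :, None] + 1)
            - gammaln(N[None, None, :] - y[:, :, None] + 1)
        )
    log_binom = np.where(N[None, None, :] >= y[:, :, None], log_binom, -np.inf)
    with np.errstate(invalid="ignore"):
        det = (
            log_binom
            + y[:, :, None] * logp[:, None, None]
            + (N[None, None, :] - y[:, :, None]) * log1mp[:, None, None]
        ).sum(axis=1)
    # p == 1 makes (N - y) * log(0) produce nan at N == y (0 * -inf); fix to 0 there
    det = np.where(np.isnan(det), -np.inf, det)
    if np.any(p >= 1.0):
        exact = N[None, :] == (y.sum(axis=1) / n_visits)[:, None]
        all_equal = (y == y[:, :1]).all(axis=1)
        det_p1 = np.where(exact & all_equal[:, None], 0.0, -np.inf)
        det = np.where((p >= 1.0)[:, None], det_p1, det)
    per_unit = logsumexp(log_pois + det, axis=1)
    return float(per_unit.sum())


def _starting_values(data: NMixtureData) -> np.ndarray:
    lam0 = np.log(data.counts.max(axis=1).mean() + 0.1)
    return np.concatenate(
        [[lam0], np.zeros(data.n_covs), np.zeros(data.n_years)]  # logit(0.5) = 0
    )


def fit_nmixture(data: NMixtureData, spec: NMixtureSpec | None = None) -> NMixtureFit:
    """Maximum-likelihood fit with K-stability check and numerical SEs."""
    spec = spec or NMixtureSpec()
    if data.counts.max() == 0:
        raise NonIdentifiableError("all counts are zero: lambda and p not separable")
    if data.counts.shape[1] < 2:
        raise NonIdentifiableError("need >= 2 visits per unit")

    K = spec.K if spec.K is not None else int(data.counts.max()) + 100
    x0 = _starting_values(data)

    result = None
    for _ in range(6):  # double K until the likelihood stabilizes
        run_spec = NMixtureSpec(K=K, k_stability_tol=spec.k_stability_tol)
        nll = lambda th: -nmix_loglik(th, data, run_spec)  # noqa: E731
        result = optimize.minimize(nll, x0, method="L-BFGS-B")
        ll_K = -result.fun
        ll_2K = nmix_loglik(result.x, data, NMixtureSpec(K=2 * K))
        if abs(ll_2K - ll_K) < spec.k_stability_tol:
            break
        x0 = result.x
        K *= 2

    k_stable = abs(ll_2K - ll_K) < spec.k_stability_tol
    theta = result.x
    beta, alpha = _split_params(theta, data.n_covs)

    # monotone-likelihood pathology: p -> 0 with lambda -> infinity
    non_ident = bool(expit(alpha).max() < 1e-3 or beta[0] > 10)

    hess = approx_hess(theta, lambda th: -nmix_loglik(th, data, NMixtureSpec(K=K)))
    se = np.full(theta.shape, np.nan)
    try:
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)
        if np.all(diag > 0):
            se = np.sqrt(diag)
    except np.linalg.LinAlgError:
        pass

    return NMixtureFit(
        abundance_coefs=beta,
        abundance_se=se[: data.n_covs + 1],
        detection_coefs=alpha,
        detection_se=se[data.n_covs + 1 :],
        loglik=float(-result.fun),
        converged=bool(result.success and k_stable and not non_ident),
        non_identifiable=non_ident,
        K=K,
        covariate_names=data.covariate_names,
        year_labels=data.year_labels,
        message=str(result.message),
    )


def predict_abundance(fit: NMixtureFit, covariates: np.ndarray) -> pd.DataFrame:
    """Expected abundance per unit, exp(linear predictor), with log scale kept."""
    if not fit.converged:
        raise RuntimeError(
            "refusing to predict from a non-converged fit "
            f"(non_identifiable={fit.non_identifiable}, message={fit.message!r})"
        )
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    log_lambda = fit.abundance_coefs[0] + X @ fit.abundance_coefs[1:]
    return pd.DataFrame(
        {"log_abundance": log_lambda, "abundance": np.exp(log_lambda)}
    )


def stack_point_years(
    counts, covariate_table, species: str
) -> NMixtureData:
    """Build NMixtureData for one species from a CountArray + CovariateTable.

    Sample units are point-years ("stacked" design); the four willow
    covariates repeat across years and year labels drive detection.
    """
    from .io_design import MODEL_COVARIATES

    i = counts.species.index(species)
    y = counts.values[i]  # (L, J, K)
    L, J, V = y.shape
    units = y.transpose(1, 0, 2).reshape(L * J, V)  # year-major stacking
    X = covariate_table.matrix(MODEL_COVARIATES)
    X_rep = np.tile(X, (J, 1))
    year_idx = np.repeat(np.arange(J), L)
    return NMixtureData(
        counts=units,
        covariates=X_rep,
        year_index=year_idx,
        covariate_names=tuple(MODEL_COVARIATES),
        year_labels=tuple(counts.years),
    )
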