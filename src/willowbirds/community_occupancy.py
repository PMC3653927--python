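"""Data-augmented hierarchical multispecies multiyear occupancy model.

The observed community of n species is embedded in a superpopulation of
M = n + n_aug potential members via inclusion indicators w_i ~ Bern(Omega).
For included species, occupancy z_{ilj} at point l in year j follows a
logit-linear model in the standardized willow covariates with species-level
intercepts u_i; detection per visit follows the same covariate structure
with intercepts v_i.  (u_i, v_i) are bivariate normal across species; slopes
are normal per covariate.

Estimation is by an explicit Metropolis-within-Gibbs sampler: exact
Bernoulli full conditionals for z and for w (with z marginalized out of the
w update), vectorized random-walk Metropolis across species for intercepts
and slopes (adaptive scaling during burn-in only, targeting 0.44
acceptance), a conjugate Beta draw for Omega, conjugate normal draws for the
slope means, and scalar Metropolis for the remaining hyperparameters.
Species carrying no data information (w = 0, or no occupied cells for the
detection block) are refreshed directly from their conditional priors.

Derived quantities: total richness sum_i w_i and point-year richness
R_{lj} = sum_i w_i * psi_{ilj}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_design import MODEL_COVARIATES, CovariateTable, DetectionArray


@dataclass
class PriorSettings:
    """Hyperprior constants (diffuse defaults; recorded in run manifests).

    Omega ~ Uniform(0,1) and rho_uv ~ Uniform(-1,1) are fixed choices.
    """

    mean_sd: float = 10.0  # community means ~ Normal(0, mean_sd^2)
    sd_upper: float = 10.0  # community SDs ~ Uniform(0, sd_upper)


@dataclass
class CommunitySpec:
    n_aug: int = 32
    chains: int = 2
    iterations: int = 30000
    burn_in: int = 3000
    thin: int = 10
    covariate_names: tuple[str, ...] = MODEL_COVARIATES
    priors: PriorSettings = field(default_factory=PriorSettings)
    seed: int = 0

    def __post_init__(self):
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_aug < 0:
            raise ValueError("n_aug must be >= 0")
        if self.chains < 1:
            raise ValueError("need at least one chain")

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class PosteriorDraws:
    """Thinned draws, kept per chain for convergence diagnostics."""

    u: np.ndarray  # (chains, draws, M)
    v: np.ndarray
    beta_psi: np.ndarray  # (chains, draws, M, C)
    beta_p: np.ndarray
    w: np.ndarray  # (chains, draws, M) 0/1
    hypers: dict[str, np.ndarray]  # name -> (chains, draws)
    species: list[str]  # observed names; augmented members follow unnamed
    covariate_names: tuple[str, ...]
    points: list[str]
    years: list[int]
    n_observed: int
    rhat: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.u.shape[0]

    @property
    def n_draws(self) -> int:
        return self.u.shape[1]

    @property
    def M(self) -> int:
        return self.u.shape[2]

    def flat(self, name: str) -> np.ndarray:
        """Hyperparameter draws pooled across chains."""
        return self.hypers[name].reshape(-1)

    def total_richness(self) -> np.ndarray:
        """Posterior draws of N_tot = sum_i w_i, pooled across chains."""
        return self.w.sum(axis=-1).reshape(-1)

    def summary(self) -> pd.DataFrame:
        rows = []
        items = list(self.hypers.items()) + [
            ("N_total", self.w.sum(axis=-1).astype(float))
        ]
        for name, arr in items:
            flat = arr.reshape(-1)
            rows.append(
                {
                    "parameter": name,
                    "median": float(np.median(flat)),
                    "q2.5": float(np.quantile(flat, 0.025)),
                    "q97.5": float(np.quantile(flat, 0.975)),
                    "rhat": self.rhat.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows)


def marginal_detection_loglik(x_history, psi: float, p: float) -> float:
    """log P(history) for one point-year with occupancy z summed out.

    P = psi * p^d * (1-p)^(K-d) + (1-psi) * 1{d = 0} for d detections in
    K visits.
    """
    x = np.asarray(x_history)
    if not np.isin(x, (0, 1)).all():
        raise ValueError("history entries must be 0/1")
    if not (0 <= psi <= 1 and 0 <= p <= 1):
        raise ValueError("psi and p must lie in [0, 1]")
    d = int(x.sum())
    K = x.size
    prob = psi * p**d * (1 - p) ** (K - d)
    if d == 0:
        prob += 1 - psi
    return float(np.log(prob))


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor from >= 2 equal-length chains."""
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = arr.shape
    if n < 10:
        raise ValueError("chains too short for Rhat")
    means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else float("inf")
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


# ---------------------------------------------------------------------------
# sampler internals

_ADAPT_INTERVAL = 50


class _Adaptive:
    """Per-element random-walk proposal scales, tuned during burn-in."""

    def __init__(self, shape, init=0.3):
        self.scale = np.full(shape, init, dtype=float)
        self.accepted = np.zeros(shape, dtype=float)
        self.attempts = 0

    def record(self, accepted):
        self.accepted += accepted
        self.attempts += 1

    def adapt(self):
        if self.attempts == 0:
            return
        rate = self.accepted / self.attempts
        self.scale *= np.exp(np.clip(rate - 0.44, -0.5, 0.5))
        np.clip(self.scale, 1e-3, 10.0, out=self.scale)
        self.accepted[...] = 0.0
        self.attempts = 0


def _bvn_logpdf(u, v, mu_u, mu_v, s_u, s_v, rho):
    zu = (u - mu_u) / s_u
    zv = (v - mu_v) / s_v
    q = (zu**2 - 2 * rho * zu * zv + zv**2) / (1 - rho**2)
    return -np.log(2 * np.pi * s_u * s_v * np.sqrt(1 - rho**2)) - 0.5 * q


def _hyper_names(covariate_names):
    names = ["omega", "mu_u", "mu_v", "sigma_u", "sigma_v", "rho_uv"]
    for name in covariate_names:
        names += [
            f"mu_beta_psi_{name}",
            f"sigma_beta_psi_{name}",
            f"mu_beta_p_{name}",
            f"sigma_beta_p_{name}",
        ]
    return names


class _ChainSampler:
    """One MCMC chain over the augmented community."""

    def __init__(self, x, X, spec: CommunitySpec, seed_seq):
        self.rng = np.random.default_rng(seed_seq)
        self.spec = spec
        n, L, J, K = x.shape
        self.n, self.L, self.J, self.K = n, L, J, K
        self.M = n + spec.n_aug
        self.C = X.shape[1]
        self.X = X
        # per-cell detection counts; augmented species are all-zero
        self.d = np.zeros((self.M, L, J), dtype=np.int64)
        self.d[:n] = x.sum(axis=3)
        self.ever = self.d.sum(axis=(1, 2)) > 0

        self._init_state()
        M, C = self.M, self.C
        self.ad_u = _Adaptive(M)
        self.ad_v = _Adaptive(M)
        self.ad_bpsi = _Adaptive((M, C))
        self.ad_bp = _Adaptive((M, C))
        self.ad_hyper = _Adaptive(5 + 2 * C, init=0.2)

    def _init_state(self):
        rng, M, C = self.rng, self.M, self.C
        self.mu_u = rng.normal(0, 1)
        self.mu_v = rng.normal(0, 1)
        self.sig_u = rng.uniform(0.5, 2.0)
        self.sig_v = rng.uniform(0.5, 2.0)
        self.rho = rng.uniform(-0.5, 0.5)
        self.u = rng.normal(self.mu_u, self.sig_u, M)
        self.v = rng.normal(self.mu_v, self.sig_v, M)
        self.mu_bpsi = rng.normal(0, 0.5, C)
        self.sig_bpsi = rng.uniform(0.2, 1.0, C)
        self.mu_bp = rng.normal(0, 0.5, C)
        self.sig_bp = rng.uniform(0.2, 1.0, C)
        self.bpsi = rng.normal(self.mu_bpsi, self.sig_bpsi, (M, C))
        self.bp = rng.normal(self.mu_bp, self.sig_bp, (M, C))
        self.omega = rng.uniform(0.3, 0.9)
        self.w = np.where(self.ever, 1, rng.random(M) < 0.5).astype(np.int8)
        self.z = (self.d > 0).astype(np.int8)
        # unoccupied-but-included cells start at a coin flip
        coin = (rng.random(self.d.shape) < 0.5) & (self.w[:, None, None] == 1)
        self.z = np.maximum(self.z, coin.astype(np.int8))
        self.z[self.d > 0] = 1

    # -- latent updates ----------------------------------------------------

    def update_latents(self):
        rng = self.rng
        logit_psi = self.u[:, None] + self.bpsi_X  # (M, L)
        psi = expit(logit_psi)
        p = expit(self.v[:, None] + self.bp_X)
        q_miss = psi * (1 - p) ** self.K  # P(occupied, all visits missed)
        denom = q_miss + (1 - psi)

        # w | rest for never-detected species, z marginalized out
        log_lik1 = self.J * np.log(denom).sum(axis=1)
        log_odds = np.log(self.omega / (1 - self.omega)) + log_lik1
        pw = expit(log_odds)
        w = (rng.random(self.M) < pw).astype(np.int8)
        w[self.ever] = 1
        self.w = w

        # z | w for cells without detections
        pz = (q_miss / denom)[:, :, None]  # (M, L, 1) broadcast over years
        draw = (rng.random(self.d.shape) < pz).astype(np.int8)
        z = np.where(self.d > 0, 1, draw * self.w[:, None, None]).astype(np.int8)
        self.z = z

    # -- species-level parameters -----------------------------------------

    @property
    def bpsi_X(self):
        return self.bpsi @ self.X.T

    @property
    def bp_X(self):
        return self.bp @ self.X.T

    def _occ_loglik(self, u, bpsi_X):
        """Bernoulli z log-likelihood per species (only where w = 1)."""
        logit_psi = u[:, None] + bpsi_X
        ll = self._kz * logit_psi - self.J * np.logaddexp(0.0, logit_psi)
        return np.where(self.w > 0, ll.sum(axis=1), 0.0)

    def _det_loglik(self, v, bp_X):
        """Binomial detection log-likelihood per species over occupied cells."""
        logit_p = v[:, None] + bp_X
        ll = self._D * logit_p - self._T * np.logaddexp(0.0, logit_p)
        return ll.sum(axis=1)

    def update_species_params(self):
        rng, M, C = self.rng, self.M, self.C
        self._kz = self.z.sum(axis=2)  # (M, L)
        self._D = (self.z * self.d).sum(axis=2)  # detections in occupied cells
        self._T = self.K * self._kz
        prior_free_occ = self.w == 0
        prior_free_det = self._T.sum(axis=1) == 0

        # --- occupancy block: u then each slope column
        bpsi_X = self.bpsi_X
        cur = self._occ_loglik(self.u, bpsi_X)

        prop = self.u + rng.normal(0, 1, M) * self.ad_u.scale
        dprior = _bvn_logpdf(
            prop, self.v, self.mu_u, self.mu_v, self.sig_u, self.sig_v, self.rho
        ) - _bvn_logpdf(
            self.u, self.v, self.mu_u, self.mu_v, self.sig_u, self.sig_v, self.rho
        )
        new = self._occ_loglik(prop, bpsi_X)
        acc = np.log(rng.random(M)) < new - cur + dprior
        self.u = np.where(acc, prop, self.u)
        cur = np.where(acc, new, cur)
        self.ad_u.record(acc & ~prior_free_occ)

        for c in range(C):
            step = rng.normal(0, 1, M) * self.ad_bpsi.scale[:, c]
            prop_col = self.bpsi[:, c] + step
            bpsi_X_new = bpsi_X + np.outer(step, self.X[:, c])
            dprior = -0.5 * (
                (prop_col - self.mu_bpsi[c]) ** 2
                - (self.bpsi[:, c] - self.mu_bpsi[c]) ** 2
            ) / self.sig_bpsi[c] ** 2
            new = self._occ_loglik(self.u, bpsi_X_new)
            acc = np.log(rng.random(M)) < new - cur + dprior
            self.bpsi[:, c] = np.where(acc, prop_col, self.bpsi[:, c])
            bpsi_X = np.where(acc[:, None], bpsi_X_new, bpsi_X)
            cur = np.where(acc, new, cur)
            self.ad_bpsi.accepted[:, c] += acc & ~prior_free_occ
        self.ad_bpsi.attempts += 1

        # refresh data-free species from their conditional priors
        if prior_free_occ.any():
            idx = prior_free_occ
            cond_mean = self.mu_u + self.rho * self.sig_u / self.sig_v * (
                self.v[idx] - self.mu_v
            )
            cond_sd = self.sig_u * np.sqrt(1 - self.rho**2)
            self.u[idx] = rng.normal(cond_mean, cond_sd)
            self.bpsi[idx] = rng.normal(
                self.mu_bpsi, self.sig_bpsi, (int(idx.sum()), C)
            )

        # --- detection block: v then each slope column
        bp_X = self.bp_X
        cur = self._det_loglik(self.v, bp_X)

        prop = self.v + rng.normal(0, 1, M) * self.ad_v.scale
        dprior = _bvn_logpdf(
            self.u, prop, self.mu_u, self.mu_v, self.sig_u, self.sig_v, self.rho
        ) - _bvn_logpdf(
            self.u, self.v, self.mu_u, self.mu_v, self.sig_u, self.sig_v, self.rho
        )
        new = self._det_loglik(prop, bp_X)
        acc = np.log(rng.random(M)) < new - cur + dprior
        self.v = np.where(acc, prop, self.v)
        cur = np.where(acc, new, cur)
        self.ad_v.record(acc & ~prior_free_det)

        for c in range(C):
            step = rng.normal(0, 1, M) * self.ad_bp.scale[:, c]
            prop_col = self.bp[:, c] + step
            bp_X_new = bp_X + np.outer(step, self.X[:, c])
            dprior = -0.5 * (
                (prop_col - self.mu_bp[c]) ** 2
                - (self.bp[:, c] - self.mu_bp[c]) ** 2
            ) / self.sig_bp[c] ** 2
            new = self._det_loglik(self.v, bp_X_new)
            acc = np.log(rng.random(M)) < new - cur + dprior
            self.bp[:, c] = np.where(acc, prop_col, self.bp[:, c])
            bp_X = np.where(acc[:, None], bp_X_new, bp_X)
            cur = np.where(acc, new, cur)
            self.ad_bp.accepted[:, c] += acc & ~prior_free_det
        self.ad_bp.attempts += 1

        if prior_free_det.any():
            idx = prior_free_det
            cond_mean = self.mu_v + self.rho * self.sig_v / self.sig_u * (
                self.u[idx] - self.mu_u
            )
            cond_sd = self.sig_v * np.sqrt(1 - self.rho**2)
            self.v[idx] = rng.normal(cond_mean, cond_sd)
            self.bp[idx] = rng.normal(self.mu_bp, self.sig_bp, (int(idx.sum()), C))

    # -- hyperparameters ---------------------------------------------------

    def _bvn_total(self, mu_u, mu_v, s_u, s_v, rho):
        if not (0 < s_u <= self.spec.priors.sd_upper):
            return -np.inf
        if not (0 < s_v <= self.spec.priors.sd_upper):
            return -np.inf
        if not (-1 < rho < 1):
            return -np.inf
        ll = _bvn_logpdf(self.u, self.v, mu_u, mu_v, s_u, s_v, rho).sum()
        pr = self.spec.priors.mean_sd
        ll += -0.5 * (mu_u**2 + mu_v**2) / pr**2
        return ll

    def update_hyperparams(self):
        rng, M, C = self.rng, self.M, self.C
        pr = self.spec.priors

        # Omega | w  (Beta conjugacy with a Uniform(0,1) prior)
        s = int(self.w.sum())
        self.omega = rng.beta(1 + s, 1 + self.M - s)

        # (mu_u, mu_v, sigma_u, sigma_v, rho): scalar Metropolis sweeps
        names = ["mu_u", "mu_v", "sig_u", "sig_v", "rho"]
        cur = self._bvn_total(self.mu_u, self.mu_v, self.sig_u, self.sig_v, self.rho)
        for k, name in enumerate(names):
            vals = [self.mu_u, self.mu_v, self.sig_u, self.sig_v, self.rho]
            vals[k] += rng.normal(0, self.ad_hyper.scale[k])
            new = self._bvn_total(*vals)
            if np.log(rng.random()) < new - cur:
                self.mu_u, self.mu_v, self.sig_u, self.sig_v, self.rho = vals
                cur = new
                self.ad_hyper.accepted[k] += 1

        # slope hyperparameters per covariate
        for beta, mus, sigs, off in (
            (self.bpsi, self.mu_bpsi, self.sig_bpsi, 5),
            (self.bp, self.mu_bp, self.sig_bp, 5 + C),
        ):
            for c in range(C):
                # conjugate normal mean with Normal(0, mean_sd^2) prior
                prec = M / sigs[c] ** 2 + 1.0 / pr.mean_sd**2
                mean = beta[:, c].sum() / sigs[c] ** 2 / prec
                mus[c] = rng.normal(mean, np.sqrt(1.0 / prec))
                # Metropolis for the SD with Uniform(0, sd_upper) prior
                ssq = np.sum((beta[:, c] - mus[c]) ** 2)
                cur_sd = sigs[c]
                prop_sd = cur_sd + rng.normal(0, self.ad_hyper.scale[off + c])
                if 0 < prop_sd <= pr.sd_upper:
                    cur_ll = -M * np.log(cur_sd) - ssq / (2 * cur_sd**2)
                    new_ll = -M * np.log(prop_sd) - ssq / (2 * prop_sd**2)
                    if np.log(rng.random()) < new_ll - cur_ll:
                        sigs[c] = prop_sd
                        self.ad_hyper.accepted[off + c] += 1
        self.ad_hyper.attempts += 1

    # -- driver ------------------------------------------------------------

    def run(self) -> dict:
        spec = self.spec
        n_keep = spec.retained_per_chain
        M, C = self.M, self.C
        out = {
            "u": np.empty((n_keep, M)),
            "v": np.empty((n_keep, M)),
            "beta_psi": np.empty((n_keep, M, C)),
            "beta_p": np.empty((n_keep, M, C)),
            "w": np.empty((n_keep, M), dtype=np.int8),
            "hypers": {
                name: np.empty(n_keep) for name in _hyper_names(spec.covariate_names)
            },
        }
        kept = 0
        for it in range(1, spec.iterations + 1):
            self.update_latents()
            self.update_species_params()
            self.update_hyperparams()
            if it <= spec.burn_in:
                if it % _ADAPT_INTERVAL == 0:
                    for ad in (
                        self.ad_u,
                        self.ad_v,
                        self.ad_bpsi,
                        self.ad_bp,
                        self.ad_hyper,
                    ):
                        ad.adapt()
            elif (it - spec.burn_in) % spec.thin == 0:
                out["u"][kept] = self.u
                out["v"][kept] = self.v
                out["beta_psi"][kept] = self.bpsi
                out["beta_p"][kept] = self.bp
                out["w"][kept] = self.w
                h = out["hypers"]
                h["omega"][kept] = self.omega
                h["mu_u"][kept] = self.mu_u
                h["mu_v"][kept] = self.mu_v
                h["sigma_u"][kept] = self.sig_u
                h["sigma_v"][kept] = self.sig_v
                h["rho_uv"][kept] = self.rho
                for c, name in enumerate(spec.covariate_names):
                    h[f"mu_beta_psi_{name}"][kept] = self.mu_bpsi[c]
                    h[f"sigma_beta_psi_{name}"][kept] = self.sig_bpsi[c]
                    h[f"mu_beta_p_{name}"][kept] = self.mu_bp[c]
                    h[f"sigma_beta_p_{name}"][kept] = self.sig_bp[c]
                kept += 1
        assert kept == n_keep
        return out


def _check_standardized(X: np.ndarray, tol: float = 1e-6) -> None:
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(np.abs(means) > tol) or np.any(np.abs(sds - 1) > tol):
        raise ValueError(
            "covariates must be standardized (mean 0, SD 1) before fitting; "
            f"got means {means} and SDs {sds}"
        )


def run_mcmc(
    x: DetectionArray, covariates: CovariateTable, spec: CommunitySpec
) -> PosteriorDraws:
    """Fit the augmented community model; returns thinned per-chain draws."""
    X = covariates.matrix(spec.covariate_names)
    _check_standardized(X)
    if X.shape[0] != len(x.points):
        raise ValueError("covariate rows do not match detection points")
    if spec.n_aug == 0:
        raise ValueError("augmentation must be applied (n_aug > 0)")

    seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    chains = []
    for seq in seeds:
        sampler = _ChainSampler(x.values, X, spec, seq)
        chains.append(sampler.run())

    stack = lambda key: np.stack([c[key] for c in chains])  # noqa: E731
    hypers = {
        name: np.stack([c["hypers"][name] for c in chains])
        for name in _hyper_names(spec.covariate_names)
    }
    draws = PosteriorDraws(
        u=stack("u"),
        v=stack("v"),
        beta_psi=stack("beta_psi"),
        beta_p=stack("beta_p"),
        w=stack("w"),
        hypers=hypers,
        species=list(x.species),
        covariate_names=tuple(spec.covariate_names),
        points=list(x.points),
        years=list(x.years),
        n_observed=len(x.species),
    )
    if spec.chains >= 2:
        for name, arr in hypers.items():
            draws.rhat[name] = gelman_rubin(arr)
        draws.rhat["N_total"] = gelman_rubin(draws.w.sum(axis=-1).astype(float))
    return draws


def _psi_draws(draws: PosteriorDraws, X: np.ndarray, members: np.ndarray):
    """w-masked occupancy probabilities per draw: (n_total_draws, M', L)."""
    u = draws.u.reshape(-1, draws.M)[:, members]
    bpsi = draws.beta_psi.reshape(-1, draws.M, len(draws.covariate_names))[:, members]
    w = draws.w.reshape(-1, draws.M)[:, members]
    logit_psi = u[:, :, None] + bpsi @ X.T
    return expit(logit_psi) * w[:, :, None]


def _group_members(draws: PosteriorDraws, grouping, group) -> np.ndarray:
    if group == "all":
        return np.arange(draws.M)
    if grouping is None or group not in grouping:
        raise KeyError(f"unknown group: {group!r}")
    names = grouping[group]
    unknown = [s for s in names if s not in draws.species]
    if unknown:
        raise KeyError(f"species not in model: {unknown}")
    return np.array([draws.species.index(s) for s in names])


def derive_richness(
    draws: PosteriorDraws,
    covariates: CovariateTable,
    grouping: dict | None = None,
    groups: tuple = ("all",),
) -> pd.DataFrame:
    """Posterior point-year richness R_lj = sum_{i in group} w_i psi_ilj.

    Covariates are constant across years, so within a draw the point richness
    repeats over years; summaries are still reported per point-year.
    Returns median and central 95% interval per (point, year, group), with
    total-richness rows (point = "_total_") appended per group.
    """
    X = covariates.matrix(draws.covariate_names)
    point_labels = list(covariates.frame.index)
    rows = []
    for group in groups:
        members = _group_members(draws, grouping, group)
        psi_w = _psi_draws(draws, X, members)  # (draws, M', L)
        R = psi_w.sum(axis=1)  # (draws, L)
        med = np.median(R, axis=0)
        lo = np.quantile(R, 0.025, axis=0)
        hi = np.quantile(R, 0.975, axis=0)
        for li, point in enumerate(point_labels):
            for year in draws.years:
                rows.append(
                    {
                        "point": point,
                        "year": year,
                        "group": group,
                        "median": float(med[li]),
                        "q2.5": float(lo[li]),
                        "q97.5": float(hi[li]),
                    }
                )
        ntot = draws.w.reshape(-1, draws.M)[:, members].sum(axis=1)
        rows.append(
            {
                "point": "_total_",
                "year": 0,
                "group": group,
                "median": float(np.median(ntot)),
                "q2.5": float(np.quantile(ntot, 0.025)),
                "q97.5": float(np.quantile(ntot, 0.975)),
            }
        )
    return pd.DataFrame(rows)


def predict_richness_surface(
    draws: PosteriorDraws,
    area: np.ndarray,
    edge_density: np.ndarray,
    covariates: CovariateTable | None = None,
) -> pd.DataFrame:
    """Expected richness over an (area, edge_density) grid, other covariates 0.

    ``area`` and ``edge_density`` are 1-D arrays on the standardized scale;
    the full grid of combinations is evaluated.  When a covariate table is
    supplied, grid nodes outside the convex hull of the observed
    (area, edge_density) pairs trigger an extrapolation warning and are
    flagged in the output.
    """
    area = np.asarray(area, dtype=float)
    edge = np.asarray(edge_density, dtype=float)
    names = list(draws.covariate_names)
    ia, ie = names.index("area"), names.index("edge_density")
    aa, ee = np.meshgrid(area, edge, indexing="ij")
    grid = np.zeros((aa.size, len(names)))
    grid[:, ia] = aa.ravel()
    grid[:, ie] = ee.ravel()

    extrapolated = np.zeros(aa.size, dtype=bool)
    if covariates is not None:
        from scipy.spatial import Delaunay, QhullError

        obs = covariates.matrix(("area", "edge_density"))
        try:
            hull = Delaunay(obs)
            extrapolated = hull.find_simplex(grid[:, [ia, ie]]) < 0
        except QhullError:  # degenerate observed cloud
            extrapolated[:] = True
        if extrapolated.any():
            warnings.warn(
                f"{int(extrapolated.sum())} grid node(s) outside the convex "
                "hull of the observed covariates (extrapolation)",
                stacklevel=2,
            )

    members = np.arange(draws.M)
    psi_w = _psi_draws(draws, grid, members)  # (draws, M, G)
    R = psi_w.sum(axis=1)  # (draws, G)
    return pd.DataFrame(
        {
            "area": aa.ravel(),
            "edge_density": ee.ravel(),
            "richness_mean": R.mean(axis=0),
            "richness_median": np.median(R, axis=0),
            "q2.5": np.quantile(R, 0.025, axis=0),
            "q97.5": np.quantile(R, 0.975, axis=0),
            "extrapolated": extrapolated,
        }
    )
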