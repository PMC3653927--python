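"""Inverse-variance pooling of per-species effect sizes into assemblage means.

Fixed-effects pooling weights each species estimate by 1/SE^2; the
random-effects variant adds a DerSimonian-Laird between-species variance
(tau^2) to every weight.  Confidence intervals are normal (z = 1.96).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

Z95 = 1.96  # conventional normal 95% multiplier


@dataclass(frozen=True)
class EffectEstimate:
    species: str
    covariate: str
    estimate: float
    se: float

    def __post_init__(self):
        if not self.se > 0:
            raise ValueError(f"{self.species}/{self.covariate}: se must be > 0")


@dataclass(frozen=True)
class PooledEffect:
    estimate: float
    se: float
    ci95: tuple[float, float]
    method: str  # "fixed" or "random"
    k: int
    tau2: float = 0.0
    q: float = 0.0

    @property
    def significant(self) -> bool:
        """CI excludes zero (the bold-face convention)."""
        lo, hi = self.ci95
        return lo > 0 or hi < 0


def _check(effects):
    effects = list(effects)
    if not effects:
        raise ValueError("no effects to pool")
    covariates = {e.covariate for e in effects}
    if len(covariates) > 1:
        raise ValueError(f"mixed covariates in one pool: {sorted(covariates)}")
    theta = np.array([e.estimate for e in effects], dtype=float)
    se = np.array([e.se for e in effects], dtype=float)
    return theta, se


def pool_fixed(effects) -> PooledEffect:
    """Fixed-effects inverse-variance pooled estimate."""
    theta, se = _check(effects)
    w = 1.0 / se**2
    est = float(np.sum(w * theta) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (theta - est) ** 2))
    return PooledEffect(
        estimate=est,
        se=pooled_se,
        ci95=(est - Z95 * pooled_se, est + Z95 * pooled_se),
        method="fixed",
        k=len(theta),
        tau2=0.0,
        q=q,
    )


def pool_random(effects) -> PooledEffect:
    """Random-effects pooling with DerSimonian-Laird tau^2."""
    theta, se = _check(effects)
    k = len(theta)
    if k < 2:
        raise ValueError("random-effects pooling needs at least 2 effects")
    w = 1.0 / se**2
    fixed = pool_fixed(effects)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (fixed.q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    est = float(np.sum(w_star * theta) / np.sum(w_star))
    pooled_se = float(np.sum(w_star) ** -0.5)
    return PooledEffect(
        estimate=est,
        se=pooled_se,
        ci95=(est - Z95 * pooled_se, est + Z95 * pooled_se),
        method="random",
        k=k,
        tau2=float(tau2),
        q=fixed.q,
    )


def pool_by_group(
    frame: pd.DataFrame, method: str = "fixed"
) -> pd.DataFrame:
    """Pool a tidy table of (species, assemblage, covariate, estimate, se).

    Returns one row per (assemblage, covariate) with estimate, CI bounds and
    the significance flag, mirroring the published table layout.
    """
    required = {"species", "assemblage", "covariate", "estimate", "se"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    pool = {"fixed": pool_fixed, "random": pool_random}[method]
    rows = []
    for (assemblage, covariate), grp in frame.groupby(
        ["assemblage", "covariate"], sort=False
    ):
        effects = [
            EffectEstimate(r.species, covariate, r.estimate, r.se)
            for r in grp.itertuples()
        ]
        pooled = pool(effects)
        rows.append(
            {
                "assemblage": assemblage,
                "covariate": covariate,
                "estimate": pooled.estimate,
                "se": pooled.se,
                "ci_low": pooled.ci95[0],
                "ci_high": pooled.ci95[1],
                "k": pooled.k,
                "tau2": pooled.tau2,
                "method": method,
                "significant": pooled.significant,
            }
        )
    return pd.DataFrame(rows)
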