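"""Synthetic survey-design emulation: landscapes, covariates, detections, counts.

Nothing here reproduces real field data; the generator matches the study
design's shape (3 regions, 37 points, 4 years, 3 visits, 17 species in three
assemblages) and the printed statistical constraints (patch-density vs
edge-density correlation above 0.7, all other covariate correlations mild),
so that every downstream model can be exercised and calibrated offline.

Every artifact draws from a sub-seed derived from the master seed with a
fixed spawn key, so modules can regenerate pieces independently and
bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_design import (
    ASSEMBLAGES,
    MODEL_COVARIATES,
    CountArray,
    CovariateTable,
    DetectionArray,
    SurveyDesign,
    standardize_covariates,
)
from .landscape_metrics import WillowMask

# fixed spawn keys for per-artifact sub-seeds
_KEY_COVARIATES = 1
_KEY_LANDSCAPE = 2
_KEY_COMMUNITY = 3
_KEY_COUNTS = 4


@dataclass
class AssemblageEffects:
    """Community-level truth per assemblage (means and between-species SDs)."""

    # occupancy slopes per covariate (area, edge, height, density)
    occ_slope_mean: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            # willow-dependent assemblages share a strong positive area effect
            "WCB": (0.99, -0.13, 0.30, 0.09),
            "WGB": (0.99, -0.13, 0.30, 0.09),
            # open-tundra: null assemblage means, spread across species
            "OT": (0.0, 0.0, 0.0, 0.0),
        }
    )
    occ_slope_sd: float = 0.5
    # abundance (log-scale) slopes per covariate
    abund_slope_mean: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "WCB": (0.27, 0.02, 0.16, 0.01),
            "WGB": (0.27, 0.02, 0.16, 0.01),
            "OT": (-0.10, -0.01, -0.04, 0.08),
        }
    )
    abund_slope_sd: float = 0.15


@dataclass
class SimConfig:
    design: SurveyDesign = field(default_factory=SurveyDesign)
    n_species: int = 17
    assemblage_sizes: tuple[int, ...] = (4, 5, 8)  # WCB, WGB, OT
    effects: AssemblageEffects = field(default_factory=AssemblageEffects)
    # occupancy / detection intercept hyperparameters (logit scale)
    mu_u: float = 0.0
    sigma_u: float = 1.25
    mu_v: float = -0.5
    sigma_v: float = 0.75
    rho_uv: float = 0.6
    # abundance intercept range (log scale), spread evenly across species
    log_lambda_range: tuple[float, float] = (-1.5, 1.0)
    detection_slope_sd: float = 0.25
    # count-model per-year detection, drawn on the logit scale
    count_p_mean_logit: float = 0.0
    count_p_sd: float = 0.5
    # covariate generator: target correlations
    pd_ed_corr: float = 0.8
    other_corr: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if sum(self.assemblage_sizes) != self.n_species:
            raise ValueError("assemblage sizes must sum to n_species")

    def subseed(self, key: int, *extra: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(self.seed, spawn_key=(key, *extra))


@dataclass
class SimTruth:
    """Every latent quantity drawn during generation."""

    params: dict = field(default_factory=dict)


def species_names(config: SimConfig) -> list[str]:
    names = []
    for a, size in zip(ASSEMBLAGES, config.assemblage_sizes):
        names.extend(f"{a}_sp{i + 1}" for i in range(size))
    return names


def assemblage_of(config: SimConfig) -> dict[str, str]:
    out = {}
    for a, size in zip(ASSEMBLAGES, config.assemblage_sizes):
        for i in range(size):
            out[f"{a}_sp{i + 1}"] = a
    return out


# ---------------------------------------------------------------------------
# covariates


#: latent-scale moments used to place raw covariates on plausible ranges
_COVARIATE_SCALES = {
    "area": (25.0, 12.0),  # percent cover, spans roughly 5-50
    "patch_density": (8.0, 3.0),  # patches per quadrat, rounded
    "edge_density": (400.0, 150.0),  # metres per quadrat
    "willow_height": (60.0, 20.0),  # cm
    "willow_density": (15.0, 5.0),  # point-frequency hits
}
_COVARIATE_ORDER = (
    "area",
    "patch_density",
    "edge_density",
    "willow_height",
    "willow_density",
)


def _correlation_matrix(config: SimConfig) -> np.ndarray:
    k = len(_COVARIATE_ORDER)
    R = np.full((k, k), config.other_corr)
    np.fill_diagonal(R, 1.0)
    i_pd = _COVARIATE_ORDER.index("patch_density")
    i_ed = _COVARIATE_ORDER.index("edge_density")
    R[i_pd, i_ed] = R[i_ed, i_pd] = config.pd_ed_corr
    eig = np.linalg.eigvalsh(R)
    if eig.min() <= 0:
        raise ValueError("requested correlation structure is not positive definite")
    return R


def simulate_covariates(
    config: SimConfig, n_points: int | None = None
) -> tuple[CovariateTable, SimTruth]:
    """Draw point covariates with the target correlation structure.

    Latents are multivariate normal; raw columns are linear transforms
    clipped to valid ranges (area to [0, 100], counts rounded nonnegative).
    The returned table is raw; standardized copies carry a ``_std`` suffix.
    """
    design = config.design
    n = n_points if n_points is not None else design.n_points
    R = _correlation_matrix(config)
    rng = np.random.default_rng(config.subseed(_KEY_COVARIATES))
    z = rng.multivariate_normal(np.zeros(len(_COVARIATE_ORDER)), R, size=n)

    cols = {}
    for j, name in enumerate(_COVARIATE_ORDER):
        mean, sd = _COVARIATE_SCALES[name]
        raw = mean + sd * z[:, j]
        if name == "area":
            raw = np.clip(raw, 0.0, 100.0)
        elif name == "patch_density":
            raw = np.round(np.maximum(raw, 0.0))
        else:
            raw = np.maximum(raw, 0.0)
        cols[name] = raw

    if n_points is None:
        points = design.point_ids()
        regions = design.point_regions()
    else:
        points = [f"P{i + 1:04d}" for i in range(n)]
        regions = ["SIM"] * n
    frame = pd.DataFrame(cols, index=pd.Index(points, name="point"))
    frame["region"] = regions
    table = CovariateTable(frame=frame)

    std = standardize_covariates(table, columns=list(_COVARIATE_ORDER))
    for name in _COVARIATE_ORDER:
        frame[f"{name}_std"] = std.frame[name]
    truth = SimTruth(params={"latent": z, "correlation_target": R})
    return CovariateTable(frame=frame), truth


# ---------------------------------------------------------------------------
# landscapes


def simulate_landscape(
    config: SimConfig,
    point: int,
    size: int = 1000,
    pixel_size: float = 0.20,
    n_clumps: int | None = None,
    clumps: list[dict] | None = None,
) -> WillowMask:
    """Binary willow mask built from overlapping elliptical thicket clumps.

    Clump number and size scale with the point index so realized percent
    cover spans roughly 5-50% across the default 37 points.  ``n_clumps``
    overrides the random clump count; ``clumps`` places explicit ellipses
    (dicts with cy, cx, a, b, theta in pixel units) instead of random ones.
    """
    rng = np.random.default_rng(config.subseed(_KEY_LANDSCAPE, point))
    n_points = config.design.n_points
    # intensity ramps across points to spread realized cover
    frac = 0.12 + 0.88 * (point % n_points) / max(n_points - 1, 1)
    if clumps is None:
        if n_clumps is None:
            n_clumps = int(rng.poisson(26 * frac))
        clumps = [
            {
                "cy": rng.uniform(0, size),
                "cx": rng.uniform(0, size),
                "a": rng.uniform(20, 120 * frac + 25),
                "b": rng.uniform(20, 120 * frac + 25),
                "theta": rng.uniform(0, np.pi),
            }
            for _ in range(n_clumps)
        ]
    grid = np.zeros((size, size), dtype=np.int8)
    rr, cc = np.mgrid[0:size, 0:size]
    for cl in clumps:
        ct, stn = np.cos(cl["theta"]), np.sin(cl["theta"])
        dy, dx = rr - cl["cy"], cc - cl["cx"]
        e = ((dx * ct + dy * stn) / cl["a"]) ** 2 + (
            (-dx * stn + dy * ct) / cl["b"]
        ) ** 2
        grid[e <= 1.0] = 1
    mask = WillowMask(grid=grid, pixel_size=pixel_size)
    mask.clumps = clumps  # ground-truth geometry for tests
    return mask


# ---------------------------------------------------------------------------
# community detection histories


def _species_truth(config: SimConfig, rng) -> dict:
    """Draw per-species occupancy/detection parameters from assemblage truth."""
    S = config.n_species
    C = len(MODEL_COVARIATES)
    cov = np.array(
        [
            [config.sigma_u**2, config.rho_uv * config.sigma_u * config.sigma_v],
            [config.rho_uv * config.sigma_u * config.sigma_v, config.sigma_v**2],
        ]
    )
    uv = rng.multivariate_normal([config.mu_u, config.mu_v], cov, size=S)
    eff = config.effects
    labels = [a for a, sz in zip(ASSEMBLAGES, config.assemblage_sizes) for _ in range(sz)]
    bpsi = np.empty((S, C))
    for i, lab in enumerate(labels):
        bpsi[i] = rng.normal(eff.occ_slope_mean[lab], eff.occ_slope_sd)
    bp = rng.normal(0.0, config.detection_slope_sd, (S, C))
    return {
        "u": uv[:, 0],
        "v": uv[:, 1],
        "beta_psi": bpsi,
        "beta_p": bp,
        "assemblage": labels,
    }


def simulate_community(
    config: SimConfig, covariates: CovariateTable
) -> tuple[DetectionArray, SimTruth]:
    """Generate detection histories from the occupancy model's own equations."""
    design = config.design
    X = _standardized_matrix(covariates)
    L = X.shape[0]
    if L != design.n_points:
        raise ValueError(
            f"covariate table has {L} points, design expects {design.n_points}"
        )
    J, K, S = design.n_years, design.visits_per_year, config.n_species
    rng = np.random.default_rng(config.subseed(_KEY_COMMUNITY))
    truth = _species_truth(config, rng)

    psi = expit(truth["u"][:, None] + truth["beta_psi"] @ X.T)  # (S, L)
    p = expit(truth["v"][:, None] + truth["beta_p"] @ X.T)
    z = (rng.random((S, L, J)) < psi[:, :, None]).astype(np.int8)
    det = rng.random((S, L, J, K)) < p[:, :, None, None]
    x = (z[:, :, :, None] * det).astype(np.int8)

    arr = DetectionArray(
        values=x,
        species=species_names(config),
        points=list(covariates.frame.index),
        years=list(design.years),
        visits=list(range(1, K + 1)),
    )
    return arr, SimTruth(params={**truth, "psi": psi, "p": p, "z": z})


def _standardized_matrix(covariates: CovariateTable) -> np.ndarray:
    """Model matrix from either *_std columns or an already-standardized table."""
    frame = covariates.frame
    std_cols = [f"{c}_std" for c in MODEL_COVARIATES]
    if all(c in frame.columns for c in std_cols):
        return frame[std_cols].to_numpy(dtype=float)
    if covariates.standardized:
        return covariates.matrix(MODEL_COVARIATES)
    raise ValueError("covariates must be standardized (or carry *_std columns)")


# ---------------------------------------------------------------------------
# counts


def simulate_counts(
    config: SimConfig, covariates: CovariateTable
) -> tuple[CountArray, SimTruth]:
    """Generate visit counts from the N-mixture generative model per species."""
    design = config.design
    X = _standardized_matrix(covariates)
    L = X.shape[0]
    if L != design.n_points:
        raise ValueError(
            f"covariate table has {L} points, design expects {design.n_points}"
        )
    J, K, S = design.n_years, design.visits_per_year, config.n_species
    rng = np.random.default_rng(config.subseed(_KEY_COUNTS))

    eff = config.effects
    labels = [a for a, sz in zip(ASSEMBLAGES, config.assemblage_sizes) for _ in range(sz)]
    C = len(MODEL_COVARIATES)
    slopes = np.empty((S, C))
    for i, lab in enumerate(labels):
        slopes[i] = rng.normal(eff.abund_slope_mean[lab], eff.abund_slope_sd)
    lo, hi = config.log_lambda_range
    intercepts = np.linspace(lo, hi, S)
    # per-year detection on the logit scale, mildly varying
    p_year = expit(rng.normal(config.count_p_mean_logit, config.count_p_sd, (S, J)))

    lam = np.exp(intercepts[:, None] + slopes @ X.T)  # (S, L)
    N = rng.poisson(lam[:, :, None] * np.ones((S, L, J)))  # (S, L, J)
    y = rng.binomial(
        N[:, :, :, None] * np.ones((1, 1, 1, K), dtype=int),
        p_year[:, None, :, None] * np.ones((1, L, 1, K)),
    )

    arr = CountArray(
        values=y,
        species=species_names(config),
        points=list(covariates.frame.index),
        years=list(design.years),
        visits=list(range(1, K + 1)),
    )
    truth = SimTruth(
        params={
            "intercepts": intercepts,
            "slopes": slopes,
            "p_year": p_year,
            "lambda": lam,
            "N": N,
            "assemblage": labels,
        }
    )
    return arr, truth
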