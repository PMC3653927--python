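"""Tests for the augmented community occupancy model and its diagnostics."""

import math

import numpy as np
import pytest
from helpers import make_standardized_table, std_view
from scipy.special import expit

from willowbirds.community_occupancy import (
    CommunitySpec,
    PosteriorDraws,
    _ChainSampler,
    derive_richness,
    gelman_rubin,
    marginal_detection_loglik,
    predict_richness_surface,
    run_mcmc,
)
from willowbirds.io_design import CovariateTable, DetectionArray
from willowbirds.synthetic_data import SimConfig, simulate_community, simulate_covariates


def oracle_marginal(x, psi, p):
    """Two-term enumeration over the latent occupancy state z."""
    d = sum(x)
    K = len(x)
    prob_given_z1 = p**d * (1 - p) ** (K - d)
    prob_given_z0 = 1.0 if d == 0 else 0.0
    return math.log(psi * prob_given_z1 + (1 - psi) * prob_given_z0)


class TestMarginalLoglik:
    def test_no_detections_half_half(self):
        ll = marginal_detection_loglik((0, 0, 0), 0.5, 0.5)
        assert ll == pytest.approx(math.log(0.5625), abs=1e-12)

    def test_detection_forces_occupancy(self):
        ll = marginal_detection_loglik((1, 0, 0), 1.0, 0.5)
        assert ll == pytest.approx(math.log(0.125), abs=1e-12)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(1, 6))
        x = rng.integers(0, 2, K)
        psi = rng.uniform(0.01, 0.99)
        p = rng.uniform(0.01, 0.99)
        assert marginal_detection_loglik(x, psi, p) == pytest.approx(
            oracle_marginal(list(x), psi, p), abs=1e-12
        )

    def test_invalid_history_rejected(self):
        with pytest.raises(ValueError):
            marginal_detection_loglik((0, 2), 0.5, 0.5)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            marginal_detection_loglik((0, 0), 1.5, 0.5)


class TestGelmanRubin:
    def test_identical_white_noise_near_one(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=2000)
        assert abs(gelman_rubin([chain, chain.copy()]) - 1.0) < 0.01

    def test_separated_chains_blow_up(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 500)
        b = rng.normal(10, 1, 500)
        assert gelman_rubin([a, b]) > 5

    def test_hand_formula_on_small_chains(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(2, 50))
        means = chains.mean(axis=1)
        W = chains.var(axis=1, ddof=1).mean()
        B = 50 * means.var(ddof=1)
        expected = math.sqrt(((49 / 50) * W + B / 50) / W)
        assert gelman_rubin(chains) == pytest.approx(expected, abs=1e-12)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin([np.zeros(100)])

    def test_constant_identical_chains(self):
        assert gelman_rubin([np.ones(50), np.ones(50)]) == 1.0


def tiny_problem(seed=0, n_points=8, n_species=3):
    rng = np.random.default_rng(seed)
    table = make_standardized_table(rng.normal(size=(n_points, 4)))
    x = rng.integers(0, 2, size=(n_species, n_points, 2, 3)).astype(np.int8)
    arr = DetectionArray(
        values=x,
        species=[f"s{i}" for i in range(n_species)],
        points=list(table.frame.index),
        years=[2005, 2006],
        visits=[1, 2, 3],
    )
    return arr, table


def tiny_spec(seed=0, **kw):
    defaults = dict(n_aug=5, chains=2, iterations=200, burn_in=50, thin=3, seed=seed)
    defaults.update(kw)
    return CommunitySpec(**defaults)


class TestRunMcmc:
    def test_deterministic_under_seed(self):
        x, table = tiny_problem()
        a = run_mcmc(x, table, tiny_spec(seed=9))
        b = run_mcmc(x, table, tiny_spec(seed=9))
        np.testing.assert_array_equal(a.u, b.u)
        np.testing.assert_array_equal(a.w, b.w)
        for name in a.hypers:
            np.testing.assert_array_equal(a.hypers[name], b.hypers[name])

    def test_seed_changes_draws(self):
        x, table = tiny_problem()
        a = run_mcmc(x, table, tiny_spec(seed=9))
        b = run_mcmc(x, table, tiny_spec(seed=10))
        assert not np.array_equal(a.u, b.u)

    def test_retained_draw_bookkeeping(self):
        spec = CommunitySpec(iterations=30000, burn_in=3000, thin=10)
        assert spec.retained_per_chain == 2700
        x, table = tiny_problem()
        small = run_mcmc(x, table, tiny_spec(iterations=250, burn_in=50, thin=4))
        assert small.n_draws == (250 - 50) // 4
        assert small.n_chains == 2

    def test_observed_species_always_included(self):
        x, table = tiny_problem(seed=3)
        draws = run_mcmc(x, table, tiny_spec(seed=3))
        n_obs = draws.n_observed
        # every observed species was detected somewhere in this fixture
        assert draws.w[:, :, :n_obs].min() == 1
        ntot = draws.w.sum(axis=-1)
        assert ntot.min() >= n_obs
        assert ntot.max() <= draws.M

    def test_z_respects_detections_inside_sampler(self):
        x, table = tiny_problem(seed=4)
        spec = tiny_spec(seed=4)
        sampler = _ChainSampler(
            x.values, table.matrix(), spec, np.random.SeedSequence(1)
        )
        for _ in range(25):
            sampler.update_latents()
            sampler.update_species_params()
            sampler.update_hyperparams()
            assert np.all(sampler.z[sampler.d > 0] == 1)
            assert np.all(sampler.z[sampler.w == 0] == 0)

    def test_non_standardized_covariates_rejected(self):
        x, table = tiny_problem()
        raw = CovariateTable(
            frame=table.frame * 3.0 + 1.0, standardized=True
        )
        with pytest.raises(ValueError, match="standardized"):
            run_mcmc(x, raw, tiny_spec())

    def test_missing_augmentation_rejected(self):
        x, table = tiny_problem()
        with pytest.raises(ValueError, match="augmentation"):
            run_mcmc(x, table, tiny_spec(n_aug=0))

    def test_rhat_attached(self):
        x, table = tiny_problem()
        draws = run_mcmc(x, table, tiny_spec())
        assert "mu_u" in draws.rhat and np.isfinite(draws.rhat["mu_u"])


def manual_draws(u, beta_area, w, points, n_draws=1):
    """Hand-built PosteriorDraws with given species intercepts/area slopes."""
    u = np.asarray(u, dtype=float)
    M = u.size
    C = 4
    bpsi = np.zeros((M, C))
    bpsi[:, 0] = beta_area
    shape = (1, n_draws)
    return PosteriorDraws(
        u=np.broadcast_to(u, shape + (M,)).copy(),
        v=np.zeros(shape + (M,)),
        beta_psi=np.broadcast_to(bpsi, shape + (M, C)).copy(),
        beta_p=np.zeros(shape + (M, C)),
        w=np.broadcast_to(np.asarray(w, dtype=np.int8), shape + (M,)).copy(),
        hypers={},
        species=[f"s{i}" for i in range(M)],
        covariate_names=("area", "edge_density", "willow_height", "willow_density"),
        points=points,
        years=[2005],
        n_observed=M,
    )


class TestDeriveRichness:
    def test_deterministic_sum(self):
        # species 1 occupies both points; species 2 only the second
        table = CovariateTable(
            frame=__import__("pandas").DataFrame(
                {
                    "area": [-1.0, 1.0],
                    "edge_density": [0.0, 0.0],
                    "willow_height": [0.0, 0.0],
                    "willow_density": [0.0, 0.0],
                },
                index=["P1", "P2"],
            ),
            standardized=True,
        )
        draws = manual_draws(u=[50.0, 0.0], beta_area=[0.0, 100.0], w=[1, 1],
                             points=["P1", "P2"])
        out = derive_richness(draws, table)
        by_point = out[out["point"] != "_total_"].set_index("point")["median"]
        assert by_point["P1"] == pytest.approx(1.0, abs=1e-10)
        assert by_point["P2"] == pytest.approx(2.0, abs=1e-10)

    def test_ten_coinflip_species_give_five(self):
        table = make_standardized_table(np.random.default_rng(0).normal(size=(3, 4)))
        frame = table.frame.copy()
        frame[:] = 0.0  # psi evaluated at the covariate means
        flat = CovariateTable(frame=frame, standardized=True)
        draws = manual_draws(u=[0.0] * 10, beta_area=[0.0] * 10, w=[1] * 10,
                             points=list(frame.index))
        out = derive_richness(draws, flat)
        vals = out[out["point"] != "_total_"]["median"]
        assert np.allclose(vals, 5.0)

    def test_linearity_of_posterior_mean(self):
        x, table = tiny_problem(seed=6)
        draws = run_mcmc(x, table, tiny_spec(seed=6))
        X = table.matrix()
        u = draws.u.reshape(-1, draws.M)
        b = draws.beta_psi.reshape(-1, draws.M, 4)
        w = draws.w.reshape(-1, draws.M)
        psi = expit(u[:, :, None] + b @ X.T) * w[:, :, None]
        mean_of_sum = psi.sum(axis=1).mean(axis=0)
        sum_of_means = psi.mean(axis=0).sum(axis=0)
        np.testing.assert_allclose(mean_of_sum, sum_of_means, atol=1e-10)

    def test_zero_slopes_equalize_points(self):
        table = make_standardized_table(np.random.default_rng(1).normal(size=(6, 4)))
        draws = manual_draws(u=[0.3, -0.4], beta_area=[0.0, 0.0], w=[1, 1],
                             points=list(table.frame.index))
        out = derive_richness(draws, table)
        vals = out[out["point"] != "_total_"]["median"].to_numpy()
        assert np.ptp(vals) < 1e-12

    def test_assemblage_grouping(self):
        table = make_standardized_table(np.random.default_rng(2).normal(size=(4, 4)))
        draws = manual_draws(u=[50.0, 50.0, 50.0], beta_area=[0.0] * 3, w=[1, 1, 1],
                             points=list(table.frame.index))
        grouping = {"WCB": ["s0", "s1"], "OT": ["s2"]}
        out = derive_richness(draws, table, grouping=grouping, groups=("WCB", "OT"))
        wcb = out[(out["group"] == "WCB") & (out["point"] != "_total_")]["median"]
        assert np.allclose(wcb, 2.0)

    def test_unknown_group_rejected(self):
        table = make_standardized_table(np.random.default_rng(3).normal(size=(4, 4)))
        draws = manual_draws(u=[0.0], beta_area=[0.0], w=[1],
                             points=list(table.frame.index))
        with pytest.raises(KeyError):
            derive_richness(draws, table, grouping={}, groups=("nope",))


class TestRichnessSurface:
    def _draws_and_table(self, slopes, n_species=4):
        rng = np.random.default_rng(10)
        table = make_standardized_table(rng.normal(size=(12, 4)))
        return (
            manual_draws(
                u=rng.normal(0, 0.5, n_species),
                beta_area=slopes,
                w=[1] * n_species,
                points=list(table.frame.index),
            ),
            table,
        )

    def test_zero_node_matches_derive_richness(self):
        draws, table = self._draws_and_table([0.4, 0.2, -0.1, 0.3])
        frame = table.frame.copy()
        frame[:] = 0.0
        flat = CovariateTable(frame=frame, standardized=True)
        at_mean = derive_richness(draws, flat)
        expected = at_mean[at_mean["point"] != "_total_"]["median"].iloc[0]
        surface = predict_richness_surface(draws, [0.0], [0.0])
        assert surface["richness_median"].iloc[0] == pytest.approx(expected, abs=1e-10)

    def test_monotone_in_area_when_slopes_positive(self):
        draws, _ = self._draws_and_table([0.5, 0.8, 0.3, 1.1])
        surface = predict_richness_surface(draws, np.linspace(-2, 2, 7), [0.0])
        vals = surface.sort_values("area")["richness_mean"].to_numpy()
        assert np.all(np.diff(vals) > 0)

    def test_grid_matches_pointwise_evaluation(self):
        draws, table = self._draws_and_table([0.4, -0.2, 0.6, 0.1])
        area = np.array([-1.0, 0.0, 1.0])
        edge = np.array([-0.5, 0.0, 0.5])
        surface = predict_richness_surface(draws, area, edge)
        import pandas as pd

        for _, row in surface.iterrows():
            frame = pd.DataFrame(
                {
                    "area": [row["area"]],
                    "edge_density": [row["edge_density"]],
                    "willow_height": [0.0],
                    "willow_density": [0.0],
                },
                index=["G"],
            )
            node = CovariateTable(frame=frame, standardized=True)
            point = derive_richness(draws, node)
            expected = point[point["point"] != "_total_"]["median"].iloc[0]
            assert row["richness_median"] == pytest.approx(expected, abs=1e-10)

    def test_extrapolation_warns(self):
        draws, table = self._draws_and_table([0.2, 0.2, 0.2, 0.2])
        with pytest.warns(UserWarning, match="convex hull"):
            predict_richness_surface(draws, [40.0], [0.0], covariates=table)


class TestSimulationSmoke:
    def test_short_fit_on_generated_data(self):
        cfg = SimConfig(seed=21)
        cov, _ = simulate_covariates(cfg)
        x, truth = simulate_community(cfg, cov)
        spec = CommunitySpec(
            n_aug=8, chains=2, iterations=400, burn_in=100, thin=5, seed=2
        )
        draws = run_mcmc(x, std_view(cov), spec)
        assert draws.n_draws == 60
        # total richness should sit at or above the observed species count
        assert draws.total_richness().min() >= (x.values.sum(axis=(1, 2, 3)) > 0).sum()
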