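import numpy as np
import pytest
from scipy import stats

from carsae.car_model import (
    ModelConfig,
    RegionDataset,
    car_full_conditional,
    gaussian_car_smooth,
    log_posterior,
    posterior_prevalence,
    run_mcmc,
)
from carsae.geography import adjacency_from_edges
from carsae.synthetic_data import generate_study, grid_graph


def make_dataset(graph, N, y, x=None):
    n = graph.n_regions
    if x is None:
        x = np.empty((n, 0))  # intercept-only design
    return RegionDataset(tuple(graph.region_ids), N, y, x)


class TestModelConfig:
    def test_defaults_match_weak_hyperpriors(self):
        cfg = ModelConfig()
        assert (cfg.alpha_u, cfg.beta_u, cfg.alpha_v, cfg.beta_v) == (1, 0.5, 1, 0.01)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"variant": "bogus"},
            {"alpha_u": 0.0},
            {"burn_in": 500, "n_iterations": 500},
            {"thinning": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelConfig(**kwargs)

    def test_variant_structure_flags(self):
        assert ModelConfig(variant="icar_only").rho_fixed == 1.0
        assert ModelConfig(variant="iid_only").has_structured is False
        assert ModelConfig(variant="leroux").rho_fixed is None


class TestCarFullConditional:
    def test_equal_neighbors_give_neighbor_value(self, grid5, rng):
        u = np.full(grid5.n_regions, 0.37)
        mean, _ = car_full_conditional(u, 12, grid5, tau2_u=1.0, rho=1.0)
        assert mean == pytest.approx(0.37)

    def test_icar_direct_substitution(self, path4):
        # region b has neighbours a and c with values 1 and 3
        u = np.array([1.0, 0.0, 3.0, 0.0])
        mean, var = car_full_conditional(u, 1, path4, tau2_u=2.0, rho=1.0)
        assert mean == pytest.approx(2.0)
        assert var == pytest.approx(1.0)

    def test_independence_limit(self, path4, rng):
        u = rng.standard_normal(4)
        mean, var = car_full_conditional(u, 1, path4, tau2_u=2.0, rho=0.0)
        assert mean == 0.0
        assert var == pytest.approx(2.0)

    def test_leroux_interpolates_continuously(self, path4, rng):
        """The conditional mean/variance are continuous in rho and hit the
        ICAR formula at rho=1."""
        u = rng.standard_normal(4)
        m1, v1 = car_full_conditional(u, 2, path4, 0.7, rho=1.0)
        m9, v9 = car_full_conditional(u, 2, path4, 0.7, rho=1.0 - 1e-9)
        assert m9 == pytest.approx(m1, abs=1e-6)
        assert v9 == pytest.approx(v1, abs=1e-6)

    def test_isolated_region_with_icar_rejected(self):
        g = adjacency_from_edges([1, 2, 3], [(1, 2)])
        with pytest.raises(ValueError, match="[Ii]solated"):
            car_full_conditional(np.zeros(3), 2, g, 1.0, rho=1.0)


class TestLogPosterior:
    def brute_force(self, state, data, graph, config):
        """Independent term-by-term summation with scipy densities."""
        X = np.column_stack([np.ones(data.n_regions), data.covariate])
        coef = np.asarray(state["coef"])
        eta = X @ coef + state["u"] + state["v"]
        p = 1 / (1 + np.exp(-eta))
        obs = data.observed_mask()
        lp = stats.binom.logpmf(data.y[obs], data.N[obs], p[obs]).sum()
        lp += stats.norm.logpdf(coef, 0, config.beta_prior_sd).sum()
        # Leroux MVN prior for u via its dense precision matrix
        D = np.diag(graph.neighbor_counts.astype(float))
        P = (state["rho"] * (D - graph.W) + (1 - state["rho"]) * np.eye(graph.n_regions))
        P = P / state["tau2_u"]
        sign, logdet = np.linalg.slogdet(P)
        assert sign > 0
        lp += 0.5 * logdet - 0.5 * state["u"] @ P @ state["u"]
        lp += stats.norm.logpdf(state["v"], 0, np.sqrt(state["tau2_v"])).sum()
        lp += stats.gamma.logpdf(1 / state["tau2_u"], config.alpha_u, scale=1 / config.beta_u)
        lp += stats.gamma.logpdf(1 / state["tau2_v"], config.alpha_v, scale=1 / config.beta_v)
        return float(lp)

    def make_states(self, rng, n):
        def one():
            return {
                "coef": rng.normal(0, 1, size=2),
                "u": rng.normal(0, 0.5, size=n),
                "v": rng.normal(0, 0.3, size=n),
                "tau2_u": float(rng.uniform(0.1, 2.0)),
                "tau2_v": float(rng.uniform(0.1, 2.0)),
                "rho": float(rng.uniform(0.05, 0.95)),
            }

        return one(), one()

    def test_matches_brute_force_on_3_region_instance(self, rng):
        g = adjacency_from_edges("abc", [("a", "b"), ("b", "c")])
        data = RegionDataset(("a", "b", "c"), [50, 200, 80], [4, 20, 9], rng.normal(size=3))
        cfg = ModelConfig()
        s1, s2 = self.make_states(rng, 3)
        # both implementations drop only parameter-independent constants,
        # so log-density *differences* must agree exactly
        mine = log_posterior(s1, data, g, cfg) - log_posterior(s2, data, g, cfg)
        ref = self.brute_force(s1, data, g, cfg) - self.brute_force(s2, data, g, cfg)
        assert mine == pytest.approx(ref, rel=1e-9)

    def test_doubled_data_sharpens_likelihood(self, rng):
        g = adjacency_from_edges("abc", [("a", "b"), ("b", "c")])
        cfg = ModelConfig()
        base = dict(
            u=np.zeros(3), v=np.zeros(3), tau2_u=0.5, tau2_v=0.5, rho=0.5
        )
        data1 = RegionDataset(("a", "b", "c"), [100, 100, 100], [10, 10, 10], np.zeros(3))
        data2 = RegionDataset(("a", "b", "c"), [200, 200, 200], [20, 20, 20], np.zeros(3))
        logit = np.log(0.1 / 0.9)
        at_mle = {**base, "coef": np.array([logit, 0.0])}
        off = {**base, "coef": np.array([logit + 0.5, 0.0])}
        drop1 = log_posterior(at_mle, data1, g, cfg) - log_posterior(off, data1, g, cfg)
        drop2 = log_posterior(at_mle, data2, g, cfg) - log_posterior(off, data2, g, cfg)
        assert drop1 > 0
        assert drop2 > drop1  # more data, sharper peak around the MLE

    def test_zero_u_leaves_only_normalizing_term(self, path4):
        """With u = 0 the CAR quadratic form vanishes: the rho-dependence
        reduces to the prior normalizing constant (log-determinant)."""
        cfg = ModelConfig()
        data = make_dataset(path4, [50] * 4, [5] * 4)
        base = dict(
            coef=np.array([-2.0]), u=np.zeros(4), v=np.zeros(4),
            tau2_u=0.7, tau2_v=0.4,
        )
        lp3 = log_posterior({**base, "rho": 0.3}, data, path4, cfg)
        lp8 = log_posterior({**base, "rho": 0.8}, data, path4, cfg)
        D = np.diag(path4.neighbor_counts.astype(float))
        lap = D - path4.W

        def logdet(rho):
            return np.sum(np.log(np.linalg.eigvalsh(rho * lap + (1 - rho) * np.eye(4))))

        assert lp3 - lp8 == pytest.approx(0.5 * (logdet(0.3) - logdet(0.8)), rel=1e-9)

    def test_nonfinite_covariate_rejected(self, path4):
        data = make_dataset(path4, [10] * 4, [1] * 4, np.array([0.0, 1.0, np.inf, 0.0]))
        with pytest.raises(ValueError, match="covariate"):
            log_posterior(
                {"coef": np.zeros(2), "u": np.zeros(4), "v": np.zeros(4),
                 "tau2_u": 1.0, "tau2_v": 1.0, "rho": 0.5},
                data, path4, ModelConfig(),
            )


class TestRunMcmc:
    CFG = dict(n_iterations=600, burn_in=200, thinning=2)

    def test_same_seed_bit_identical(self, grid5):
        s = generate_study(25, seed=3)
        data = make_dataset(s.graph, s.N, s.y, s.truth["covariate_standardized"])
        cfg = ModelConfig(seed=11, **self.CFG)
        a = run_mcmc(data, s.graph, cfg)
        b = run_mcmc(data, s.graph, cfg)
        assert np.array_equal(a.coef, b.coef)
        assert np.array_equal(a.u, b.u)
        assert np.array_equal(a.tau2_u, b.tau2_u)
        assert np.array_equal(a.rho, b.rho)

    def test_different_seeds_differ(self, grid5):
        s = generate_study(25, seed=3)
        data = make_dataset(s.graph, s.N, s.y, s.truth["covariate_standardized"])
        a = run_mcmc(data, s.graph, ModelConfig(seed=1, **self.CFG))
        b = run_mcmc(data, s.graph, ModelConfig(seed=2, **self.CFG))
        assert not np.array_equal(a.coef, b.coef)

    def test_icar_variant_rejects_isolated_regions(self):
        g = adjacency_from_edges([1, 2, 3], [(1, 2)])
        data = make_dataset(g, [50] * 3, [5] * 3)
        with pytest.raises(ValueError, match="[Ii]solated"):
            run_mcmc(data, g, ModelConfig(variant="bym", **self.CFG))

    def test_icar_draws_sum_to_zero(self, grid5):
        s = generate_study(25, seed=4)
        data = make_dataset(s.graph, s.N, s.y, s.truth["covariate_standardized"])
        samp = run_mcmc(data, s.graph, ModelConfig(variant="bym", seed=5, **self.CFG))
        assert np.allclose(samp.u.sum(axis=1), 0.0, atol=1e-9)
        assert np.all(samp.rho == 1.0)

    def test_acceptance_rates_in_healthy_band(self):
        s = generate_study(64, seed=6)
        data = make_dataset(s.graph, s.N, s.y, s.truth["covariate_standardized"])
        samp = run_mcmc(
            data, s.graph, ModelConfig(seed=7, n_iterations=2000, burn_in=800, thinning=2)
        )
        for block in ("coef", "u", "v"):
            assert 0.15 < samp.acceptance_rates[block] < 0.7

    def test_response_missing_regions_tolerated(self, grid5):
        s = generate_study(25, seed=8)
        rm = np.zeros(25, dtype=bool)
        rm[[0, 7]] = True
        data = RegionDataset(
            tuple(s.graph.region_ids), s.N, np.where(rm, 0, s.y),
            s.truth["covariate_standardized"], response_missing=rm,
        )
        samp = run_mcmc(data, s.graph, ModelConfig(seed=9, **self.CFG))
        assert np.all(np.isfinite(samp.u))

    def test_iid_only_matches_independent_oracle(self):
        """Reduced model check: with no spatial structure, the sampler's
        posterior mean of tau_v^2 agrees with an independently written
        random-scan Metropolis sampler for the same logistic-normal
        (beta-binomial-style) model, within Monte-Carlo error."""
        rng = np.random.default_rng(42)
        n = 40
        alpha_true, tau_true = -2.0, 0.35
        v_true = rng.normal(0, tau_true, n)
        N = np.full(n, 400)
        y = rng.binomial(N, 1 / (1 + np.exp(-(alpha_true + v_true))))
        # the graph is irrelevant for the iid_only variant
        g = grid_graph(5, 8)
        data = make_dataset(g, N, y)
        cfg = ModelConfig(
            variant="iid_only", seed=21, n_iterations=12_000, burn_in=4_000, thinning=4
        )
        samp = run_mcmc(data, g, cfg)

        t2_oracle = _oracle_iid_sampler(y, N, cfg, seed=77)
        mine, se_m = _mean_and_mcse(samp.tau2_v)
        ref, se_r = _mean_and_mcse(t2_oracle)
        assert abs(mine - ref) < 2 * np.hypot(se_m, se_r) + 0.01


def _oracle_iid_sampler(y, N, cfg, seed, n_iter=30_000, burn=10_000):
    """Plain random-scan Metropolis for logit(p_r) = a + v_r, written
    independently of the package sampler (own density, own moves)."""
    rng = np.random.default_rng(seed)
    n = y.size
    a, v, log_t2 = -2.0, np.zeros(n), np.log(0.1)

    def loglik(a_, v_):
        eta = a_ + v_
        return np.sum(y * eta - N * np.log1p(np.exp(eta)))

    def logpost(a_, v_, lt2):
        t2 = np.exp(lt2)
        lp = loglik(a_, v_)
        lp += stats.norm.logpdf(a_, 0, 10.0)
        lp += stats.norm.logpdf(v_, 0, np.sqrt(t2)).sum()
        # gamma(alpha_v, beta_v) on the precision, plus log-Jacobians of
        # precision = exp(-lt2): d(prec)/d(lt2) = -prec
        prec = 1 / t2
        lp += stats.gamma.logpdf(prec, cfg.alpha_v, scale=1 / cfg.beta_v) + np.log(prec)
        return lp

    cur = logpost(a, v, log_t2)
    keep = []
    for it in range(n_iter):
        a_new = a + 0.05 * rng.standard_normal()
        cand = logpost(a_new, v, log_t2)
        if np.log(rng.random()) < cand - cur:
            a, cur = a_new, cand
        v_new = v.copy()
        j = rng.integers(n)
        v_new[j] += 0.3 * rng.standard_normal()
        cand = logpost(a, v_new, log_t2)
        if np.log(rng.random()) < cand - cur:
            v, cur = v_new, cand
        lt_new = log_t2 + 0.3 * rng.standard_normal()
        cand = logpost(a, v, lt_new)
        if np.log(rng.random()) < cand - cur:
            log_t2, cur = lt_new, cand
        if it >= burn and it % 10 == 0:
            keep.append(np.exp(log_t2))
    return np.asarray(keep)


def _mean_and_mcse(x, n_batches=20):
    """Batch-means Monte-Carlo standard error of a chain mean."""
    x = np.asarray(x)
    m = len(x) // n_batches
    batches = x[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return float(x.mean()), float(batches.std(ddof=1) / np.sqrt(n_batches))


class TestPosteriorPrevalence:
    def _samples_with_eta(self, value, n_draws, n):
        from carsae.car_model import PosteriorSamples

        return PosteriorSamples(
            coef=np.full((n_draws, 1), value),
            u=np.zeros((n_draws, n)),
            v=np.zeros((n_draws, n)),
            tau2_u=np.ones(n_draws),
            tau2_v=np.ones(n_draws),
            rho=np.full(n_draws, 0.5),
            acceptance_rates={},
            seed=0,
        )

    def test_zero_linear_predictor_gives_half(self, path4):
        data = make_dataset(path4, [10] * 4, [5] * 4)
        est = posterior_prevalence(
            self._samples_with_eta(0.0, 50, 4), data, ModelConfig()
        )
        assert est.mean == pytest.approx(np.full(4, 0.5))
        assert est.sd == pytest.approx(np.zeros(4))

    def test_constant_negative_predictor(self, path4):
        data = make_dataset(path4, [10] * 4, [1] * 4)
        est = posterior_prevalence(
            self._samples_with_eta(-2.2, 50, 4), data, ModelConfig()
        )
        assert est.mean == pytest.approx(np.full(4, 0.09975), abs=1e-4)

    def test_posterior_sd_shrinks_with_sample_size(self):
        """Matched synthetic pair: scaling every N_r up tightens the
        posterior for every region."""
        s = generate_study(36, seed=10)
        cfg = ModelConfig(seed=13, n_iterations=3000, burn_in=1000, thinning=2)
        x = s.truth["covariate_standardized"]
        p = s.truth["p"]
        rng = np.random.default_rng(0)
        N_small = np.full(36, 60)
        N_big = np.full(36, 2400)
        res = {}
        for tag, N in (("small", N_small), ("big", N_big)):
            y = rng.binomial(N, p)
            data = make_dataset(s.graph, N, y, x)
            samp = run_mcmc(data, s.graph, cfg)
            res[tag] = posterior_prevalence(samp, data, cfg).sd.mean()
        assert res["big"] < res["small"]


class TestGaussianCarSmooth:
    def test_constant_field_reproduced(self, grid5):
        z = np.full(25, 7.5)
        z[[3, 17]] = np.nan
        out = gaussian_car_smooth(z, grid5, n_iterations=800, burn_in=300, seed=1)
        assert out == pytest.approx(np.full(25, 7.5), abs=0.05)

    def test_missing_region_pulled_to_neighbor_value(self, grid5):
        z = np.full(25, 950.0)
        z[12] = np.nan  # interior cell, all 8 neighbours at 950
        out = gaussian_car_smooth(z, grid5, n_iterations=800, burn_in=300, seed=2)
        assert out[12] == pytest.approx(950.0, abs=2.0)

    def test_all_missing_rejected(self, grid5):
        with pytest.raises(ValueError):
            gaussian_car_smooth(np.full(25, np.nan), grid5)

    def test_isolated_region_rejected(self):
        g = adjacency_from_edges([1, 2, 3], [(1, 2)])
        with pytest.raises(ValueError, match="isolated"):
            gaussian_car_smooth(np.array([1.0, 2.0, np.nan]), g)


class TestConfigYaml:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            "variant: bym\nn_iterations: 2000\nburn_in: 500\nbeta_v: 0.1\nseed: 9\n"
        )
        cfg = ModelConfig.from_yaml(path)
        assert cfg.variant == "bym"
        assert cfg.n_iterations == 2000
        assert cfg.beta_v == 0.1

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("bogus_knob: 3\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            ModelConfig.from_yaml(path)
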