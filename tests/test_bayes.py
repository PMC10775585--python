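"""Priors, posterior sampling, and MCMC convergence diagnostics."""

import numpy as np
import pytest

import poolmove as pm
from poolmove.bayes import RHAT_CONVERGED
from tests.conftest import random_theta


class TestBuildPriors:
    def test_informative_interior_pool_means(self, design6):
        priors = pm.build_priors("informative", design6)
        mean = priors.row_mean(3)  # Peoria: neighbors La Grange, Starved Rock
        assert mean[2] * 100 == pytest.approx(63.0, abs=1.0)   # stay
        assert mean[1] * 100 == pytest.approx(16.0, abs=1.0)   # one adjacent
        assert mean[5] * 100 == pytest.approx(1.5, abs=0.3)    # one non-adjacent
        assert priors.phi_beta == (2.0, 1.0)

    def test_end_pool_self_mean_rises(self, design6):
        # an end pool has one neighbor, so normalization boosts staying
        priors = pm.build_priors("informative", design6)
        assert priors.row_mean(1)[0] > 0.70

    def test_rows_scale_to_concentration(self, design6):
        priors = pm.build_priors("informative", design6, concentration=50.0)
        assert np.allclose(priors.movement_shapes.sum(axis=1), 50.0)

    def test_uninformative_is_flat(self, design6):
        priors = pm.build_priors("uninformative", design6)
        assert np.allclose(priors.row_mean(2), 1 / 6)
        assert priors.phi_beta == (1.0, 1.0)

    def test_nonpositive_concentration_rejected(self, design6):
        with pytest.raises(ValueError, match="concentration"):
            pm.build_priors("informative", design6, concentration=0.0)


class TestLogPrior:
    def test_uniform_prior_is_constant(self, design6):
        priors = pm.build_priors("uninformative", design6)
        rng = np.random.default_rng(5)
        values = [pm.log_prior(random_theta(6, rng), priors) for _ in range(5)]
        assert np.allclose(values, values[0], atol=1e-9)

    def test_beta21_closed_form(self):
        design = pm.StudyDesign(pools=("A", "B"), start=(2012, 3), n_occasions=3)
        priors = pm.build_priors("informative", design, concentration=2.0)
        # with all shapes summing to 2 per row for M=2: shapes are (2a, 2b)
        flat = pm.PriorSpec(phi_beta=(2.0, 1.0), rho_beta=(2.0, 1.0),
                            movement_shapes=np.ones((2, 2)), mode="custom")
        theta = pm.ParameterSet(phi=0.5, psi=np.full((2, 2), 0.5),
                                rho=np.full((2, 4), 0.5))
        # 9 Beta(2,1) terms, each log(2 * 0.5) = 0; Dirichlet(1,1) terms are 0
        assert pm.log_prior(theta, flat) == pytest.approx(0.0, abs=1e-12)
        assert priors.mode == "informative"

    def test_dirichlet_closed_form(self):
        shapes = np.array([[2.0, 1.0, 1.0]] * 3)
        priors = pm.PriorSpec(phi_beta=(1.0, 1.0), rho_beta=(1.0, 1.0),
                              movement_shapes=shapes, mode="custom")
        psi = np.array([[0.5, 0.25, 0.25]] * 3)
        theta = pm.ParameterSet(phi=0.5, psi=psi, rho=np.full((3, 4), 0.5))
        # each row: log[Gamma(4)/Gamma(2) * 0.5] = log 3
        assert pm.log_prior(theta, priors) == pytest.approx(3 * np.log(3.0))

    def test_boundary_returns_infinite_not_raise(self):
        shapes = np.full((2, 2), 2.0)
        priors = pm.PriorSpec(phi_beta=(2.0, 1.0), rho_beta=(2.0, 1.0),
                              movement_shapes=shapes, mode="custom")
        theta = pm.ParameterSet(phi=0.5, psi=np.array([[1.0, 0.0], [0.5, 0.5]]),
                                rho=np.full((2, 4), 0.5))
        assert pm.log_prior(theta, priors) == -np.inf


class TestDiagnostics:
    def test_iid_chains_look_converged(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal((4, 1000))
        r = pm.rhat(draws)
        assert 1.0 <= r < RHAT_CONVERGED
        bulk, tail = pm.ess(draws)
        assert bulk == pytest.approx(4000, rel=0.2)
        assert tail == pytest.approx(4000, rel=0.2)

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal((2, 500))
        draws[1] += 10.0
        assert pm.rhat(draws) > 1.5

    def test_ar1_ess_matches_theory(self):
        rho = 0.9
        rng = np.random.default_rng(2)
        n = 2000
        draws = np.empty((4, n))
        for c in range(4):
            x = 0.0
            eps = rng.standard_normal(n) * np.sqrt(1 - rho**2)
            for i in range(n):
                x = rho * x + eps[i]
                draws[c, i] = x
        bulk, _ = pm.ess(draws)
        expected = 4 * n * (1 - rho) / (1 + rho)
        assert bulk == pytest.approx(expected, rel=0.3)

    def test_zero_variance_warns_nan(self):
        draws = np.ones((2, 100))
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            assert np.isnan(pm.rhat(draws))


def _fake_posterior(chain_means, within_sd, n=400, seed=0):
    rng = np.random.default_rng(seed)
    draws = np.stack(
        [m + within_sd * rng.standard_normal((n, 1)) for m in chain_means]
    )
    return pm.PosteriorResult(
        draws=draws, parameter_names=["psi[1,2]"],
        rhat=np.array([np.nan]), ess_bulk=np.array([np.nan]),
        ess_tail=np.array([np.nan]),
        posterior_mean=draws.reshape(-1, 1).mean(0),
        posterior_sd=draws.reshape(-1, 1).std(0),
        accept_rate=np.ones(len(chain_means)), n_warmup=0, seed=seed,
        prior_mode="custom",
    )


class TestDetectMultimodality:
    def test_agreeing_chains_give_empty_report(self):
        result = _fake_posterior([0.5, 0.5, 0.5, 0.5], within_sd=0.02)
        assert pm.detect_multimodality(result) == []

    def test_outlier_chain_clustered(self):
        result = _fake_posterior([0.1, 0.1, 0.1, 0.8], within_sd=0.02)
        reports = pm.detect_multimodality(result)
        assert len(reports) == 1
        assert reports[0]["parameter"] == "psi[1,2]"
        assert reports[0]["clusters"] == ([1, 2, 3], [4])

    def test_sparse_pool_parameters_are_weakly_identified(self):
        # movement into and detection at the nearly-unobserved pool trade off
        # against each other: under flat priors their marginals stay close to
        # prior-wide while well-observed pools' parameters pin down sharply
        cfg = pm.sparse_state_scenario(1)
        histories, _ = pm.simulate_histories(cfg)
        priors = pm.build_priors("uninformative", cfg.design)
        result = pm.sample_posterior(
            histories, cfg.design, priors, n_chains=2, n_warmup=150, n_iter=250,
            seed=12,
        )
        sd = dict(zip(result.parameter_names, result.posterior_sd))
        sparse_rho = np.mean([sd[f"rho[3,{s}]"] for s in range(1, 5)])
        seen_rho = np.mean([sd[f"rho[1,{s}]"] for s in range(1, 5)])
        assert sparse_rho > 5 * seen_rho
        assert sd["psi[3,1]"] > 5 * sd["psi[1,3]"]


class TestSamplePosterior:
    def test_same_seed_reproduces_draws(self, design2, theta2):
        cfg = pm.SimulationConfig(design=design2, theta_true=theta2,
                                  release_counts=(15, 15), seed=3)
        histories, _ = pm.simulate_histories(cfg)
        priors = pm.build_priors("informative", design2)
        kwargs = dict(n_chains=2, n_warmup=60, n_iter=60, seed=7)
        a = pm.sample_posterior(histories, design2, priors, **kwargs)
        b = pm.sample_posterior(histories, design2, priors, **kwargs)
        assert np.array_equal(a.draws, b.draws)

    def test_draws_are_valid_parameter_sets(self, design2, theta2):
        cfg = pm.SimulationConfig(design=design2, theta_true=theta2,
                                  release_counts=(15, 15), seed=3)
        histories, _ = pm.simulate_histories(cfg)
        priors = pm.build_priors("informative", design2)
        res = pm.sample_posterior(histories, design2, priors, n_chains=2,
                                  n_warmup=60, n_iter=60, seed=7)
        assert np.all(res.draws >= 0.0) and np.all(res.draws <= 1.0)
        for draw in res.draws.reshape(-1, res.draws.shape[-1])[::25]:
            pm.unpack(draw, 2)  # raises if any row is off the simplex

    def test_prior_only_sampling_recovers_prior_means(self, design6):
        priors = pm.build_priors("informative", design6)
        res = pm.sample_posterior([], design6, priors, n_chains=2,
                                  n_warmup=300, n_iter=600, seed=21)
        idx = res.parameter_names.index("psi[3,2]")  # interior, adjacent
        prior_mean = priors.row_mean(3)[1]
        mcse = res.posterior_sd[idx] / np.sqrt(max(res.ess_bulk[idx], 1.0))
        assert res.posterior_mean[idx] == pytest.approx(
            prior_mean, abs=max(3 * mcse, 0.01)
        )
        # phi under Beta(2,1) has prior mean 2/3
        phi_idx = res.parameter_names.index("phi")
        assert res.posterior_mean[phi_idx] == pytest.approx(2 / 3, abs=0.03)

    def test_doubling_data_contracts_posterior(self, design2, theta2):
        design = pm.StudyDesign(pools=("A", "B"), start=(2012, 3), n_occasions=12)
        sds = []
        for n_per_pool in (50, 100):
            cfg = pm.SimulationConfig(design=design, theta_true=theta2,
                                      release_counts=(n_per_pool, n_per_pool),
                                      seed=6)
            histories, _ = pm.simulate_histories(cfg)
            priors = pm.build_priors("informative", design)
            res = pm.sample_posterior(histories, design, priors, n_chains=2,
                                      n_warmup=250, n_iter=500, seed=8)
            sds.append(res.posterior_sd.mean())
        assert sds[1] < sds[0]

    def test_too_few_chains_rejected(self, design2):
        priors = pm.build_priors("informative", design2)
        with pytest.raises(ValueError, match="chains"):
            pm.sample_posterior([], design2, priors, n_chains=1)
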