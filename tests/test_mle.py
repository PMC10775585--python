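"""Packing, penalized objective, L-BFGS-B fitting, and variance machinery."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import poolmove as pm
from poolmove.mle import PENALTY_BASE, finite_difference_hessian
from tests.conftest import random_theta


class TestPackUnpack:
    def test_free_parameter_count_six_pools(self):
        assert pm.n_free_parameters(6) == 55
        assert len(pm.free_parameter_names(6)) == 55

    def test_identity_movement_packs_to_zeros(self):
        theta = pm.ParameterSet(phi=0.9, psi=np.eye(6), rho=np.full((6, 4), 0.5))
        v = pm.pack(theta)
        assert np.allclose(v[:30], 0.0)

    @given(seed=st.integers(0, 10_000))
    def test_roundtrip_on_feasible_vectors(self, seed):
        theta = random_theta(4, np.random.default_rng(seed))
        v = pm.pack(theta)
        again = pm.pack(pm.unpack(v, 4))
        assert np.allclose(again, v, atol=1e-12)

    def test_unpack_rejects_infeasible_row(self):
        v = pm.pack(random_theta(3, np.random.default_rng(0)))
        v[0], v[1] = 0.7, 0.5  # row-1 off-diagonals sum to 1.2
        with pytest.raises(ValueError, match="infeasible movement row"):
            pm.unpack(v, 3)


@pytest.fixture(scope="module")
def stay_data():
    design = pm.StudyDesign(pools=("A", "B"), start=(2012, 3), n_occasions=8)
    theta = pm.ParameterSet(phi=1.0, psi=np.eye(2), rho=np.ones((2, 4)))
    cfg = pm.SimulationConfig(design=design, theta_true=theta,
                              release_counts=(10, 10), seed=0)
    histories, _ = pm.simulate_histories(cfg)
    return design, theta, histories


class TestNegativeLogLikelihood:
    def test_zero_at_certain_truth(self, stay_data):
        design, theta, histories = stay_data
        assert pm.negative_log_likelihood(pm.pack(theta), histories, design) == 0.0

    def test_truth_beats_perturbation(self, recovery_data2, design2, theta2):
        _, histories, _ = recovery_data2
        v = pm.pack(theta2)
        worse = v.copy()
        worse[0] = min(1.0, worse[0] + 0.1)
        assert pm.negative_log_likelihood(v, histories, design2) < (
            pm.negative_log_likelihood(worse, histories, design2)
        )

    def test_infeasible_vector_hits_penalty(self):
        # a 3-pool row whose off-diagonals sum past 1 must cost more than
        # any feasible fit could
        design = pm.StudyDesign(pools=("A", "B", "C"), start=(2012, 3), n_occasions=6)
        v = pm.pack(random_theta(3, np.random.default_rng(0)))
        v[0], v[1] = 0.7, 0.5
        assert pm.negative_log_likelihood(v, [], design) >= PENALTY_BASE


class TestFitMLE:
    def test_two_pool_recovery_within_three_se(self, recovery_data2, design2, theta2):
        _, histories, _ = recovery_data2
        result = pm.fit_mle(histories, design2)
        assert result.converged
        err = np.abs(result.free_vector - pm.pack(theta2))
        assert np.all(err <= 3.0 * result.se + 1e-9)

    def test_unobserved_transition_estimates_to_zero(self, design2):
        # ample data, but nobody ever moves B -> A
        theta = pm.ParameterSet(
            phi=1.0, psi=np.array([[0.9, 0.1], [0.0, 1.0]]), rho=np.full((2, 4), 0.9)
        )
        cfg = pm.SimulationConfig(design=design2, theta_true=theta,
                                  release_counts=(60, 60), release_window=(1, 6),
                                  seed=4)
        histories, _ = pm.simulate_histories(cfg)
        result = pm.fit_mle(histories, design2, compute_se=False)
        psi_ba = result.theta_hat.psi[1, 0]
        assert psi_ba <= 1e-4

    def test_multistart_agrees_on_well_identified_data(self, recovery_data2, design2):
        _, histories, _ = recovery_data2
        rng = np.random.default_rng(11)
        other = pm.pack(random_theta(2, rng))
        result = pm.fit_mle(
            histories, design2, init=[pm.default_init(design2), other],
            compute_se=False,
        )
        assert len(result.all_neg_log_lik) == 2
        assert result.neg_log_lik <= min(result.all_neg_log_lik) + 1e-9
        # refit from the second start alone lands on the same optimum
        alone = pm.fit_mle(histories, design2, init=other, compute_se=False)
        assert np.allclose(alone.free_vector, result.free_vector, atol=1e-4)

    def test_infeasible_init_is_rejected(self):
        design = pm.StudyDesign(pools=("A", "B", "C"), start=(2012, 3), n_occasions=6)
        theta = random_theta(3, np.random.default_rng(2))
        cfg = pm.SimulationConfig(design=design, theta_true=theta,
                                  release_counts=(5, 5, 5), seed=2)
        histories, _ = pm.simulate_histories(cfg)
        bad = pm.default_init(design)
        bad[0] = bad[1] = 0.9  # row-1 off-diagonals sum to 1.8
        with pytest.raises(ValueError, match="feasible start"):
            pm.fit_mle(histories, design, init=bad)


class TestPseudoVariance:
    def test_pd_inverse_unchanged(self):
        h = np.array([[4.0, 1.0], [1.0, 3.0]])
        cov = pm.pseudo_variance(h)
        assert np.allclose(cov, np.linalg.inv(h), atol=1e-12)

    def test_indefinite_inverse_clipped_to_pd(self):
        h = np.diag([1.0, -100.0])  # inverse diag(1, -0.01)
        cov = pm.pseudo_variance(h)
        eigs = np.linalg.eigvalsh(cov)
        assert np.all(eigs > 0)
        assert cov[0, 1] == pytest.approx(0.0, abs=1e-15)
        assert cov[0, 0] == pytest.approx(1.0, rel=1e-9)

    def test_quadratic_recovers_known_hessian(self):
        a = np.array([[5.0, 1.0, 0.0], [1.0, 3.0, 0.5], [0.0, 0.5, 2.0]])
        f = lambda x: 0.5 * (x - 0.4) @ a @ (x - 0.4)
        h = finite_difference_hessian(f, np.full(3, 0.5), step=1e-4)
        assert np.allclose(h, a, atol=1e-5)
        assert np.allclose(pm.pseudo_variance(h), np.linalg.inv(a), atol=1e-5)

    def test_all_zero_row_names_coordinate(self):
        h = np.eye(3)
        h[1] = 0.0
        h[:, 1] = 0.0
        with pytest.raises(ValueError, match=r"\[1\]"):
            pm.pseudo_variance(h)


class TestDeltaMethod:
    def test_independent_offdiagonals(self):
        cov = np.diag([0.01] * 5 + [99.0] * 50)  # row 1 of a 6-pool model
        assert pm.delta_method_se(cov, 1, 6) == pytest.approx(np.sqrt(0.05))

    def test_anticorrelated_pair_cancels(self):
        cov = np.zeros((55, 55))
        cov[0, 0] = cov[1, 1] = 0.01
        cov[0, 1] = cov[1, 0] = -0.01
        assert pm.delta_method_se(cov, 1, 6) == pytest.approx(0.0, abs=1e-12)

    def test_matches_parametric_bootstrap(self, design2, theta2):
        # SE of the derived diagonal vs the spread of refitted estimates
        design = pm.StudyDesign(pools=("A", "B"), start=(2012, 3), n_occasions=12)
        cfg = pm.SimulationConfig(design=design, theta_true=theta2,
                                  release_counts=(75, 75), seed=9)
        histories, _ = pm.simulate_histories(cfg)
        fit = pm.fit_mle(histories, design)
        delta_se = pm.delta_method_se(fit.covariance, 1, 2)
        boots = []
        for b in range(30):
            bcfg = pm.SimulationConfig(design=design, theta_true=fit.theta_hat,
                                       release_counts=(75, 75), seed=1000 + b)
            bh, _ = pm.simulate_histories(bcfg)
            bfit = pm.fit_mle(bh, design, init=fit.free_vector, compute_se=False)
            boots.append(bfit.theta_hat.psi[0, 0])
        boot_se = float(np.std(boots, ddof=1))
        assert delta_se == pytest.approx(boot_se, rel=0.25)
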