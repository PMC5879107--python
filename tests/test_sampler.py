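import numpy as np
import pytest
from scipy import stats

from otubayes.data_model import CountData
from otubayes.likelihood import nb_logpmf, sample_nb
from otubayes.sampler import (
    MCMCConfig,
    empirical_constraints,
    imputation_probabilities,
    init_state,
    joint_update_r_alpha0,
    log_joint,
    log_mean_matrix,
    mean_matrix,
    run_mcmc,
    plugin_size_factors,
)
from otubayes.synthetic import SimConfig, simulate_dataset


class TestNBLogpmf:
    def test_zero_count_closed_form(self):
        # P(0) = (1/(1+s*mu))^(1/s); mu=s=1 gives 1/2
        assert nb_logpmf(0, 1.0, 1.0) == pytest.approx(np.log(0.5), abs=1e-12)

    def test_truncated_sum_normalizes(self):
        y = np.arange(10_001)
        total = np.exp(nb_logpmf(y, 5.0, 0.3)).sum()
        assert abs(total - 1.0) < 1e-8

    def test_poisson_limit(self):
        y = np.arange(51)
        nb = nb_logpmf(y, 7.0, 1e-8)
        po = stats.poisson.logpmf(y, 7.0)
        assert np.max(np.abs(nb - po)) < 1e-4

    def test_matches_scipy_nbinom(self):
        # independent parameterization check: size=1/s, p=1/(1+s*mu)
        y, mu, s = np.arange(30), 4.2, 0.45
        ref = stats.nbinom.logpmf(y, 1 / s, 1 / (1 + s * mu))
        assert np.allclose(nb_logpmf(y, mu, s), ref, atol=1e-12)

    def test_sampled_moments(self, rng):
        mu, s = 6.0, 0.5
        x = sample_nb(np.full(1_000_000, mu), s, rng)
        var = mu + mu**2 * s
        assert abs(x.mean() - mu) < 4 * np.sqrt(var / x.size)
        # SE of the sample variance via the fourth moment, approximated normal-ish
        assert abs(x.var() - var) < 0.05 * var

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            nb_logpmf(1, -1.0, 0.5)
        with pytest.raises(ValueError):
            nb_logpmf(1, 1.0, 0.0)


@pytest.fixture(scope="module")
def small_state():
    cfg = SimConfig(
        J=5, n_times=6, years=1.0, replicates=(2,), P_continuous=2,
        categorical_levels=(3,), missing_prob=0.3,
    )
    data, covars, _ = simulate_dataset(cfg, seed=9)
    mc = MCMCConfig(
        iterations=20, burn_in=10, L_r=4, L_alpha=4, M=3, t1p=0.2, t2p=0.2
    )
    rng = np.random.default_rng(4)
    state = init_state(data, covars, mc, rng)
    return data, covars, state, rng


class TestMeanMatrix:
    def test_all_zero_parameters_give_unit_means(self, small_state):
        import copy

        data, covars, state, _ = small_state
        st = copy.deepcopy(state)
        st.regression.beta[:] = 0
        st.baseline.r_tilde[:] = 0
        st.baseline.alpha0_tilde[:] = 0
        st.baseline.temporal.theta[:] = 0
        X = covars.design_matrix(st.cat_values)[data.sample_time_index]
        assert np.allclose(mean_matrix(st, data, X), 1.0)

    def test_shift_invariance_bit_exact(self, small_state):
        import copy

        data, covars, state, _ = small_state
        X = covars.design_matrix(state.cat_values)[data.sample_time_index]
        base = mean_matrix(state, data, X)
        st = copy.deepcopy(state)
        delta = 0.625  # power of two: the shift is exact in floating point
        st.baseline.r_tilde = st.baseline.r_tilde + delta
        st.baseline.alpha0_tilde = st.baseline.alpha0_tilde - delta
        shifted = mean_matrix(st, data, X)
        assert np.array_equal(base, shifted)

    def test_matches_bruteforce_product(self, small_state):
        data, covars, state, _ = small_state
        X = covars.design_matrix(state.cat_values)[data.sample_time_index]
        mu = mean_matrix(state, data, X)
        bl = state.baseline
        Zs = bl.basis.Z[data.sample_time_index]
        for i in range(4):
            for j in range(3):
                expect = (
                    np.exp(bl.r_tilde[i])
                    * np.exp(bl.alpha0_tilde[j])
                    * np.exp(Zs[i] @ bl.temporal.theta[:, j])
                    * np.exp(X[i] @ state.regression.beta[j])
                )
                assert mu[i, j] == pytest.approx(expect, rel=1e-12)

    def test_overflow_guard(self, small_state):
        import copy

        data, covars, state, _ = small_state
        st = copy.deepcopy(state)
        st.baseline.r_tilde[:] = 800.0
        X = covars.design_matrix(st.cat_values)[data.sample_time_index]
        with pytest.raises(OverflowError):
            mean_matrix(st, data, X)


class TestEmpiricalConstraints:
    def test_hand_computed_example(self):
        data = CountData([[1, 1], [2, 2]], [0.0, 1.0], [1, 1])
        r_prime, a_prime = plugin_size_factors(data)
        assert np.allclose(r_prime, [1 / 3, 2 / 3])
        assert np.allclose(a_prime, [3.0, 3.0])
        c_r, c_a = empirical_constraints(data)
        assert c_r == pytest.approx((np.log(1 / 3) + np.log(2 / 3)) / 2)
        assert c_a == pytest.approx(np.log(3.0))

    def test_equal_row_sums_give_uniform_r(self):
        data = CountData([[3, 1], [1, 3], [2, 2]], [0.0, 1.0, 2.0], [1, 1, 1])
        r_prime, _ = plugin_size_factors(data)
        assert np.allclose(r_prime, 1 / 3)

    def test_duplicating_samples_shifts_constraints_oppositely(self, rng):
        """Duplicating every sample halves each r' (total count doubles) and
        doubles each alpha0', so c_r drops by log 2, c_alpha rises by log 2
        and their sum — the scale of the baseline g — is invariant."""
        counts = rng.integers(1, 30, size=(4, 6))
        d1 = CountData(counts, np.arange(4.0), np.ones(4, int))
        dup = CountData(
            np.repeat(counts, 2, axis=0),
            np.repeat(np.arange(4.0), 2),
            np.tile([1, 2], 4),
        )
        c_r1, c_a1 = empirical_constraints(d1)
        c_r2, c_a2 = empirical_constraints(dup)
        assert c_r2 == pytest.approx(c_r1 - np.log(2), rel=1e-12)
        assert c_a2 == pytest.approx(c_a1 + np.log(2), rel=1e-12)
        assert c_r2 + c_a2 == pytest.approx(c_r1 + c_a1, rel=1e-12)

    def test_all_zero_otu_excluded_with_warning(self):
        counts = np.array([[5, 0], [3, 0]])
        data = CountData(counts, [0.0, 1.0], [1, 1])
        with pytest.warns(UserWarning, match="all-zero"):
            _, c_a = empirical_constraints(data)
        assert np.isfinite(c_a)


class TestJointMove:
    def test_likelihood_term_exactly_invariant(self, small_state):
        data, covars, state, _ = small_state
        X = covars.design_matrix(state.cat_values)[data.sample_time_index]
        lm = log_mean_matrix(state, data, X)
        delta = 0.375
        bl = state.baseline
        lm_shift = (
            (bl.r_tilde + delta)[:, None]
            + (bl.alpha0_tilde - delta)[None, :]
            + bl.basis.Z[data.sample_time_index] @ bl.temporal.theta
            + X @ state.regression.beta.T
        )
        assert np.max(np.abs(lm - lm_shift)) < 1e-12

    def test_zero_step_always_accepts(self, small_state):
        import copy

        data, covars, state, _ = small_state
        st = copy.deepcopy(state)
        _, accepted = joint_update_r_alpha0(st, np.random.default_rng(0), step=0.0)
        assert accepted


class TestImputation:
    def test_uniform_when_beta_zero(self, small_state):
        import copy

        data, covars, state, _ = small_state
        st = copy.deepcopy(state)
        st.regression.beta[:] = 0.0
        i, q = np.argwhere(covars.missing_mask)[0]
        p = imputation_probabilities(st, data, covars, i, q)
        assert np.allclose(p, 1.0 / covars.n_levels[q], atol=1e-12)

    def test_matches_bruteforce_enumeration(self, small_state):
        data, covars, state, _ = small_state
        i, q = np.argwhere(covars.missing_mask)[0]
        p = imputation_probabilities(state, data, covars, i, q)
        # brute force: evaluate the full NB likelihood of the whole table
        # for each candidate level
        C = covars.n_levels[q]
        ll = np.empty(C)
        cats = state.cat_values.copy()
        for lev in range(C):
            cats[i, q] = lev
            X = covars.design_matrix(cats)[data.sample_time_index]
            mu = mean_matrix(state, data, X)
            ll[lev] = nb_logpmf(data.counts, mu, state.s[None, :]).sum()
        brute = np.exp(ll - ll.max())
        brute /= brute.sum()
        assert np.allclose(p, brute, atol=1e-10)
        assert p.argmax() == brute.argmax()


class TestConditionalTargets:
    """Density-ratio spot checks: each Metropolis update's target must be
    the corresponding slice of the joint density."""

    def test_r_tilde_slice(self, small_state):
        import copy

        from otubayes.constrained_mixture import mixture_logpdf
        from otubayes.likelihood import nb_loglik_mu_terms

        data, covars, state, _ = small_state
        X = covars.design_matrix(state.cat_values)[data.sample_time_index]
        st2 = copy.deepcopy(state)
        st2.baseline.r_tilde[0] += 0.3
        lhs = log_joint(st2, data, covars) - log_joint(state, data, covars)
        lm1 = log_mean_matrix(state, data, X)
        lm2 = log_mean_matrix(st2, data, X)
        rhs = (
            nb_loglik_mu_terms(data.counts[0], lm2[0], state.s).sum()
            - nb_loglik_mu_terms(data.counts[0], lm1[0], state.s).sum()
            + mixture_logpdf(st2.baseline.r_tilde[0], state.baseline.mix_r)
            - mixture_logpdf(state.baseline.r_tilde[0], state.baseline.mix_r)
        )
        # gamma-function terms cancel since s is unchanged
        assert lhs == pytest.approx(rhs, abs=1e-8)

    def test_s_slice(self, small_state):
        import copy

        data, covars, state, _ = small_state
        st2 = copy.deepcopy(state)
        st2.s = state.s.copy()
        st2.s[1] *= 1.5
        lhs = log_joint(st2, data, covars) - log_joint(state, data, covars)
        X = covars.design_matrix(state.cat_values)[data.sample_time_index]
        mu = mean_matrix(state, data, X)
        rhs = (
            nb_logpmf(data.counts[:, 1], mu[:, 1], st2.s[1]).sum()
            - nb_logpmf(data.counts[:, 1], mu[:, 1], state.s[1]).sum()
            + (state.a_s - 1) * (np.log(st2.s[1]) - np.log(state.s[1]))
            - state.b_s * (st2.s[1] - state.s[1])
        )
        assert lhs == pytest.approx(rhs, abs=1e-8)

    def test_theta_slice(self, small_state):
        import copy

        from otubayes.likelihood import nb_loglik_mu_terms

        data, covars, state, _ = small_state
        X = covars.design_matrix(state.cat_values)[data.sample_time_index]
        st2 = copy.deepcopy(state)
        st2.baseline.temporal.theta[1, 2] += 0.4
        lhs = log_joint(st2, data, covars) - log_joint(state, data, covars)
        lm1 = log_mean_matrix(state, data, X)
        lm2 = log_mean_matrix(st2, data, X)
        tau2 = state.baseline.temporal.tau2[2]
        rhs = (
            nb_loglik_mu_terms(data.counts[:, 2], lm2[:, 2], state.s[2]).sum()
            - nb_loglik_mu_terms(data.counts[:, 2], lm1[:, 2], state.s[2]).sum()
            + (state.baseline.temporal.theta[1, 2] ** 2
               - st2.baseline.temporal.theta[1, 2] ** 2) / (2 * tau2)
        )
        assert lhs == pytest.approx(rhs, abs=1e-8)

    def test_tau2_conditional_density_ratio(self, small_state):
        import copy

        data, covars, state, _ = small_state
        tmp = state.baseline.temporal
        M = tmp.theta.shape[0]
        j = 0
        ig = stats.invgamma(
            tmp.a_tau + M / 2, scale=tmp.b_tau + 0.5 * np.sum(tmp.theta[:, j] ** 2)
        )
        st2 = copy.deepcopy(state)
        st2.baseline.temporal.tau2 = tmp.tau2.copy()
        st2.baseline.temporal.tau2[j] *= 1.8
        lhs = log_joint(st2, data, covars) - log_joint(state, data, covars)
        rhs = ig.logpdf(st2.baseline.temporal.tau2[j]) - ig.logpdf(tmp.tau2[j])
        assert lhs == pytest.approx(rhs, abs=1e-10)


class TestRunMCMC:
    def test_draw_count_formula(self):
        cfg = MCMCConfig(iterations=25_000, burn_in=10_000, thin=2)
        assert cfg.n_draws == 7500

    def test_reproducible_and_shapes(self, tiny_fit):
        data, covars, truth, draws, mc = tiny_fit
        assert draws.n_draws == mc.n_draws == 100
        assert draws.beta.shape == (100, data.J, covars.P)
        assert np.all(np.isfinite(draws.log_post))
        draws2 = run_mcmc(data, covars, mc, seed=7)
        assert np.array_equal(draws.beta, draws2.beta)
        assert np.array_equal(draws.log_post, draws2.log_post)
        draws3 = run_mcmc(data, covars, mc, seed=8)
        assert not np.array_equal(draws.beta, draws3.beta)

    def test_logpost_cache_equals_recomputation(self, tiny_fit):
        """The stored log_post of retained draws must match a from-scratch
        evaluation at the fully reconstructed state."""
        data, covars, truth, draws, mc = tiny_fit
        for d in (0, draws.n_draws // 2, draws.n_draws - 1):
            state = draws.state_at(d)
            assert log_joint(state, data, covars) == pytest.approx(
                draws.log_post[d], abs=1e-8
            )

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            MCMCConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCConfig(thin=0)

    def test_draws_save_load_roundtrip(self, tiny_fit, tmp_path):
        from otubayes.sampler import PosteriorDraws

        data, covars, truth, draws, mc = tiny_fit
        draws.save(tmp_path / "draws")
        back = PosteriorDraws.load(tmp_path / "draws")
        assert np.array_equal(back.beta, draws.beta)
        assert np.array_equal(back.log_post, draws.log_post)
        assert back.config.iterations == mc.iterations
        assert back.c_r == draws.c_r and back.c_alpha == draws.c_alpha

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            "mcmc:\n  iterations: 400\n  burn_in: 100\n  thin: 3\n"
            "basis:\n  M: 5\n  t1p: 0.5\n  t2p: 0.5\n"
            "constraints: [-3.0, 4.0]\n"
        )
        cfg = MCMCConfig.from_yaml(path)
        assert cfg.iterations == 400 and cfg.M == 5
        assert cfg.constraints == (-3.0, 4.0)
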