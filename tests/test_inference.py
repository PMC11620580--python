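"""Normalisation, distance, priors, the ABC-MH kernel, tuning and ESS."""

import math

import numpy as np
import pytest

from filacol.inference import (
    DEFAULT_PRIORS,
    AbcMcmc,
    Chain,
    ReplicateStats,
    abc_mh_step,
    distance,
    effective_sample_size,
    normalise_stats,
    prior_log_density,
    reference_stats,
)
from filacol.simulate import ColonyStallError

REF = ReplicateStats(
    I_B_vec=[10.0, 20.0, 30.0],
    I_F_vec=[0.2, 0.5, 0.6],
    I_R_vec=[0.3, 0.4, 0.8],
)


class TestReplicateStats:
    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            ReplicateStats([1.0], [2.0], [3.0])

    def test_degenerate_statistic_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ReplicateStats([1.0, 1.0], [0.1, 0.2], [0.3, 0.4])

    def test_from_array_roundtrip(self):
        arr = np.array([[10, 0.2, 0.3], [20, 0.5, 0.4], [30, 0.6, 0.8]])
        ref = ReplicateStats.from_array(arr)
        np.testing.assert_array_equal(ref.I_B_vec, [10, 20, 30])
        assert ref.n_rep == 3


class TestNormalisation:
    def test_min_maps_to_zero_and_max_to_one(self):
        np.testing.assert_allclose(normalise_stats(REF.mins, REF), [0, 0, 0])
        np.testing.assert_allclose(normalise_stats(REF.maxs, REF), [1, 1, 1])

    def test_midpoint_value(self):
        out = normalise_stats([20.0, 0.5, 0.4], REF)
        assert out[0] == pytest.approx(0.5)

    def test_reference_mean_of_symmetric_vector(self):
        # I_B = (10, 20, 30): the mean 20 normalises to 0.5
        assert reference_stats(REF)[0] == pytest.approx(0.5)

    def test_reference_matches_hand_computation(self):
        s_bar = reference_stats(REF)
        for i, (vec, mean) in enumerate(
            [(REF.I_B_vec, 20.0),
             (REF.I_F_vec, 1.3 / 3),
             (REF.I_R_vec, 0.5)]
        ):
            expect = (mean - vec.min()) / (vec.max() - vec.min())
            assert s_bar[i] == pytest.approx(expect, abs=1e-12)


class TestDistance:
    def test_zero_at_reference(self):
        s = np.array([0.3, 0.7, 0.5])
        assert distance(s, s) == 0.0

    def test_unit_offset_from_origin(self):
        assert distance([1, 1, 1], [0, 0, 0]) == pytest.approx(
            math.sqrt(3) / 3, abs=1e-12
        )

    def test_weighted_single_component(self):
        assert distance([1, 1, 0], [1, 1, 1]) == pytest.approx(
            1.0 / 6.0, abs=1e-12
        )

    def test_rms_variant(self):
        assert distance([1, 1, 1], [0, 0, 0], prefactor="rms") == pytest.approx(
            1.0, abs=1e-12
        )

    def test_nonnegative_and_asymmetric_weighting(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            a, b = rng.uniform(0, 1, 3), rng.uniform(0, 1, 3)
            assert distance(a, b) >= 0
        # Eq-weighting depends on which argument is the reference
        assert distance([1, 0, 0], [0, 1, 1]) != distance([0, 1, 1], [1, 0, 0])


class TestPriorLogDensity:
    def test_beta22_density_at_half(self):
        # Beta(2,2) pdf at 0.5 is 6 * 0.25 = 1.5
        lp = prior_log_density(
            [0.5] * 5, priors=[(2, 2)] * 5
        )
        assert lp == pytest.approx(5 * math.log(1.5), abs=1e-12)

    def test_outside_support_minus_inf(self):
        assert prior_log_density([0.5, 0.5, 0.5, 0.5, 1.0]) == -np.inf
        assert prior_log_density([-0.1, 0.5, 0.5, 0.5, 0.5]) == -np.inf

    def test_uniform_prior_log_density_zero(self):
        assert prior_log_density([0.3] * 5, priors=[(1, 1)] * 5) == 0.0


class TestAbcMhStep:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        theta = np.full(5, 0.5)
        lp = prior_log_density(theta, [(1, 1)] * 5)
        chol = 0.01 * np.eye(5)
        return rng, theta, lp, chol

    def test_distance_above_epsilon_rejects(self):
        rng, theta, lp, chol = self._setup()
        for _ in range(50):
            t2, _, acc, rho = abc_mh_step(
                theta, lp, lambda t, r: 10.0, epsilon=1.0, proposal_chol=chol,
                rng=rng, priors=[(1, 1)] * 5,
            )
            assert not acc and np.array_equal(t2, theta)

    def test_close_simulation_with_flat_prior_always_accepts(self):
        rng, theta, lp, chol = self._setup()
        n_acc = sum(
            abc_mh_step(theta, lp, lambda t, r: 0.0, 1.0, chol, rng,
                        [(1, 1)] * 5)[2]
            for _ in range(50)
        )
        assert n_acc == 50

    def test_out_of_support_rejected_without_simulating(self):
        rng = np.random.default_rng(1)
        theta = np.full(5, 0.999)  # huge steps leave the unit cube
        lp = prior_log_density(theta, [(1, 1)] * 5)
        calls = []

        def sim(t, r):
            calls.append(t)
            return 0.0

        rejected_without_sim = 0
        for _ in range(200):
            before = len(calls)
            _, _, acc, _ = abc_mh_step(
                theta, lp, sim, 1.0, 10.0 * np.eye(5), rng, [(1, 1)] * 5
            )
            if not acc and len(calls) == before:
                rejected_without_sim += 1
        assert rejected_without_sim > 0

    def test_epsilon_inf_short_circuits_simulator(self):
        rng, theta, lp, chol = self._setup()

        def sim(t, r):  # pragma: no cover - must never run
            raise AssertionError("simulator called despite epsilon = inf")

        for _ in range(100):
            theta, lp, _, rho = abc_mh_step(
                theta, lp, sim, np.inf, chol, rng, [(1, 1)] * 5
            )
            assert np.isnan(rho)

    def test_simulator_stall_treated_as_rejection(self):
        rng, theta, lp, chol = self._setup()

        def sim(t, r):
            raise ColonyStallError("jam", None)

        with pytest.warns(UserWarning, match="stall"):
            t2, _, acc, _ = abc_mh_step(
                theta, lp, sim, 1.0, chol, rng, [(1, 1)] * 5
            )
        assert not acc and np.array_equal(t2, theta)


class TestPriorRecovery:
    def test_infinite_epsilon_samples_the_prior(self):
        # with the indicator short-circuited the chain is plain MH whose
        # stationary law is the prior; each Beta mean is recovered within
        # Monte-Carlo error (3 standard errors, autocorrelation-adjusted)
        sampler = AbcMcmc(
            epsilon=np.inf, chain_length=4000, n_chains=2, random_state=7
        ).fit(REF)
        prior_mean = np.array([a / (a + b) for a, b in DEFAULT_PRIORS])
        se = sampler.samples_.std(axis=0) / np.sqrt(sampler.ess_)
        assert (np.abs(sampler.posterior_mean_ - prior_mean) < 3 * se).all()

    def test_stationary_distribution_is_prior_two_sample(self):
        # detailed-balance smoke test: thinned chain draws vs direct
        # Beta draws, Kolmogorov-Smirnov at alpha = 0.01, fixed seed
        from scipy.stats import ks_2samp

        sampler = AbcMcmc(
            epsilon=np.inf, chain_length=20_000, n_chains=1, random_state=123
        ).fit(REF)
        thinned = sampler.samples_[::40]
        rng = np.random.default_rng(321)
        for j, (a, b) in enumerate(DEFAULT_PRIORS):
            direct = rng.beta(a, b, size=len(thinned))
            assert ks_2samp(thinned[:, j], direct).pvalue > 0.01

    def test_seeded_run_reproducible(self):
        kw = dict(epsilon=np.inf, chain_length=500, n_chains=2, random_state=3)
        a = AbcMcmc(**kw).fit(REF)
        b = AbcMcmc(**kw).fit(REF)
        np.testing.assert_array_equal(a.samples_, b.samples_)

    def test_accepted_states_satisfy_distance_bound(self):
        # surrogate simulator: distance falls with n_star so some accepts
        # and some rejections occur; every accepted rho must be <= epsilon
        sampler = AbcMcmc(epsilon=0.3, chain_length=400, n_chains=1,
                          random_state=5)
        sampler._make_simulate_distance = lambda ref, s_bar: (
            lambda t, r: abs(t[0] - 0.7) * 3 + 0.25 * r.random()
        )
        sampler.fit(REF)
        chain = sampler.chains_[0]
        rho_accepted = chain.distances[chain.accepted]
        assert np.isfinite(rho_accepted).all()
        assert (rho_accepted <= 0.3).all()

    def test_concatenation_preserves_chain_provenance(self):
        sampler = AbcMcmc(epsilon=np.inf, chain_length=100, n_chains=3,
                          random_state=2).fit(REF)
        assert [c.chain_id for c in sampler.chains_] == [0, 1, 2]
        np.testing.assert_array_equal(
            sampler.samples_[:100], sampler.chains_[0].samples
        )
        np.testing.assert_array_equal(
            sampler.samples_[100:200], sampler.chains_[1].samples
        )


class TestTune:
    def _surrogate(self, ref, s_bar):
        # cheap stand-in for the simulator: distance shrinks near the
        # "true" n_star = 0.7 with simulation noise on top
        def sim(theta, rng):
            return float(
                abs(theta[0] - 0.7) + abs(theta[4] - 0.2)
                + 0.3 * rng.random()
            )

        return sim

    def test_tuned_epsilon_below_loose_start_and_in_band(self):
        sampler = AbcMcmc(random_state=11)
        sampler._make_simulate_distance = self._surrogate
        sampler.tune(REF, pilot_iters=300)
        report = sampler.tuning_report_
        eps0 = report["history"][0][0]
        assert sampler.epsilon < eps0
        acc = report["acceptance"]
        # binomial slack around the [0.05, 0.10] band at 300 iterations
        slack = 3 * math.sqrt(0.1 * 0.9 / 300)
        assert 0.05 - slack <= acc <= 0.10 + slack

    def test_degenerate_pilot_falls_back_to_default_cov(self):
        sampler = AbcMcmc(random_state=1)
        sampler._make_simulate_distance = self._surrogate
        const = Chain(
            samples=np.tile(np.full(5, 0.5), (300, 1)),
            accepted=np.zeros(300, dtype=bool),
            distances=np.full(300, np.nan),
        )
        sampler._run_chain = (
            lambda sim, eps, chol, rng, chain_id, length: const
        )
        with pytest.warns(UserWarning, match="degenerate pilot"):
            sampler.tune(REF, pilot_iters=300, max_rounds=1)
        np.testing.assert_array_equal(
            sampler.proposal_cov, np.diag(np.full(5, 0.05**2))
        )

    def test_pilot_budget_validated(self):
        with pytest.raises(ValueError):
            AbcMcmc().tune(REF, pilot_iters=50)


class TestEffectiveSampleSize:
    def test_white_noise_near_chain_length(self):
        x = np.random.default_rng(0).normal(size=10_000)
        assert effective_sample_size(x) == pytest.approx(10_000, rel=0.10)

    def test_constant_chain_collapses_to_one(self):
        assert effective_sample_size(np.full(100, 0.3)) == 1.0

    def test_ar1_matches_closed_form(self):
        rng = np.random.default_rng(1)
        m, phi = 20_000, 0.9
        x = np.empty(m)
        x[0] = 0.0
        for i in range(1, m):
            x[i] = phi * x[i - 1] + rng.normal()
        expect = m * (1 - phi) / (1 + phi)
        assert effective_sample_size(x) == pytest.approx(expect, rel=0.20)

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            effective_sample_size(np.arange(5.0))


class TestEstimatorProtocol:
    def test_get_set_params_roundtrip(self):
        s = AbcMcmc(chain_length=123)
        p = s.get_params()
        assert p["chain_length"] == 123
        s.set_params(n_chains=7)
        assert s.n_chains == 7
        with pytest.raises(ValueError):
            s.set_params(nope=3)

    def test_credible_interval_requires_fit(self):
        with pytest.raises(AttributeError):
            AbcMcmc().credible_interval()

    def test_credible_interval_shape_and_order(self):
        s = AbcMcmc(epsilon=np.inf, chain_length=400, n_chains=1,
                    random_state=0).fit(REF)
        ci = s.credible_interval(0.9)
        assert ci.shape == (5, 2)
        assert (ci[:, 0] <= ci[:, 1]).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            AbcMcmc(priors=((1, 1),) * 4)._validate()
        with pytest.raises(ValueError):
            AbcMcmc(epsilon=-1.0)._validate()
        with pytest.raises(ValueError):
            AbcMcmc(chain_length=0)._validate()
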