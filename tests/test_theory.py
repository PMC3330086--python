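import itertools

import numpy as np
import pytest

from synchain.model import DendriticModulation, ModelParams
from synchain.phase import free_period
from synchain.theory import (
    StationaryDensity,
    TransitionModel,
    build_transition_model,
    empirical_density,
    excitation_probability,
    group_input_distribution,
    self_consistent_rate,
    siegert_rate,
    spike_response_probability,
    stationary_density_diffusion,
)

LIN = DendriticModulation.identity()


def params(**kw):
    d = dict(N=400, p_conn=0.05, p_exc=0.8, eps_exc=0.0125, eps_inh=-0.05,
             I_ext=1.5)
    d.update(kw)
    return ModelParams(**d)


def uniform_density(V_theta=1.0):
    grid = np.linspace(0.0, V_theta, 2001)
    return StationaryDensity(grid, np.ones_like(grid), 1.0, "empirical", V_theta)


class TestRates:
    def test_uncoupled_rate_is_free_rate(self):
        p = params(eps_exc=0.0, eps_inh=0.0)
        assert self_consistent_rate(p, LIN) == pytest.approx(
            1.0 / free_period(p), rel=1e-12
        )

    def test_noiseless_siegert_limit(self):
        p = params()
        assert siegert_rate(p, p.I_ext, 0.0) == pytest.approx(
            1.0 / free_period(p), rel=1e-12
        )

    def test_small_noise_approaches_noiseless_rate(self):
        p = params()
        nu0 = 1.0 / free_period(p)
        assert siegert_rate(p, p.I_ext, 1e-8) == pytest.approx(nu0, rel=1e-3)

    def test_rate_decreases_with_inhibition(self):
        rates = [
            self_consistent_rate(params(eps_inh=ei), LIN)
            for ei in (-0.02, -0.05, -0.08)
        ]
        assert rates[0] > rates[1] > rates[2]

    def test_runaway_excitation_reported(self):
        p = params(eps_exc=0.2, eps_inh=0.0)
        with pytest.raises(RuntimeError, match="bracket|cap"):
            self_consistent_rate(p, LIN)


class TestDiffusionDensity:
    def test_normalized_with_absorbing_boundary(self, ref):
        p, mod = ref
        nu = self_consistent_rate(p, mod)
        dens = stationary_density_diffusion(p, nu, mod)
        assert np.trapezoid(dens.density, dens.grid) == pytest.approx(1.0, abs=1e-9)
        assert dens.density[-1] == 0.0
        assert np.all(dens.density >= 0)

    def test_zero_noise_degenerate_branch_matches_flow_occupancy(self):
        p = params(eps_exc=0.0, eps_inh=0.0)
        dens = stationary_density_diffusion(p, 1.0 / free_period(p))
        inside = (dens.grid > 0.05) & (dens.grid < 0.95)
        expected = 1.0 / (free_period(p) * (p.I_ext - p.gamma * dens.grid[inside]))
        assert np.allclose(dens.density[inside], expected, rtol=1e-4)

    def test_small_noise_density_approaches_flow_occupancy(self):
        # scale couplings down: the diffusion solution converges to the
        # deterministic occupancy away from the boundary layer
        p = params(eps_exc=0.0125e-2, eps_inh=-0.05e-2)
        nu = self_consistent_rate(p, LIN)
        dens = stationary_density_diffusion(p, nu, LIN)
        inside = (dens.grid > 0.1) & (dens.grid < 0.9)
        expected = 1.0 / (free_period(p) * (p.I_ext - p.gamma * dens.grid[inside]))
        rel = np.abs(dens.density[inside] - expected) / expected
        assert rel.max() < 0.02


class TestEmpiricalDensity:
    def test_point_mass(self):
        p = params()
        with pytest.warns(RuntimeWarning):
            dens = empirical_density(np.full(100, 0.4), p)
        mode = dens.grid[np.argmax(dens.density)]
        assert abs(mode - 0.4) < 0.01
        assert np.trapezoid(dens.density, dens.grid) == pytest.approx(1.0, abs=1e-9)

    def test_histogram_converges_to_sampled_density(self, ref):
        p, mod = ref
        nu = self_consistent_rate(p, mod)
        target = stationary_density_diffusion(p, nu, mod)
        rng = np.random.default_rng(0)
        l1 = []
        for n in (2_000, 200_000):
            with pytest.warns(RuntimeWarning) if n < 10_000 else _nullcontext():
                est = empirical_density(target.sample(n, rng), p)
            di = np.interp(est.grid, target.grid, target.density)
            l1.append(np.trapezoid(np.abs(di - est.density), est.grid))
        assert l1[1] < l1[0]
        assert l1[1] < 0.05


class _nullcontext:
    def __enter__(self):
        return None

    def __exit__(self, *a):
        return False


class TestExcitationProbability:
    def test_zero_and_negative_inputs(self):
        dens = uniform_density()
        assert excitation_probability(0.0, dens) == 0.0
        assert excitation_probability(-0.3, dens) == 0.0

    def test_uniform_density_analytic(self):
        dens = uniform_density()
        assert excitation_probability(0.25, dens) == pytest.approx(0.25, abs=1e-6)

    def test_saturates_at_one(self):
        dens = uniform_density()
        assert excitation_probability(2.0, dens) == pytest.approx(1.0, abs=1e-9)

    def test_non_decreasing(self):
        dens = uniform_density()
        lam = np.linspace(-0.5, 1.5, 301)
        F = excitation_probability(lam, dens)
        assert np.all(np.diff(F) >= -1e-12)


class TestGroupInputDistribution:
    def test_zero_group_point_mass(self):
        m, l, pmf = group_input_distribution(0, params())
        assert pmf.shape == (1, 1) and pmf[0, 0] == 1.0

    def test_single_sender_probabilities(self):
        p = params(p_conn=0.1, p_exc=0.8)
        m, l, pmf = group_input_distribution(1, p)
        table = {(mi, li): pmf[i, j] for i, mi in enumerate(m) for j, li in enumerate(l)}
        assert table[(1, 0)] == pytest.approx(0.08)
        assert table[(0, 1)] == pytest.approx(0.02)
        assert table[(0, 0)] == pytest.approx(0.90)

    def test_sums_to_one(self):
        for g in (1, 5, 50, 200):
            _, _, pmf = group_input_distribution(g, params())
            assert pmf.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_monte_carlo_link_sampling(self):
        """Trinomial pmf agrees with direct sampling of synaptic links."""
        p = params()
        g = 50
        rng = np.random.default_rng(12)
        n = 200_000
        draws = rng.multinomial(
            g, [p.p_conn * p.p_exc, p.p_conn * p.p_inh, 1 - p.p_conn], size=n
        )
        m_vals, l_vals, pmf = group_input_distribution(g, p)
        for mi, li in [(0, 0), (1, 0), (2, 1), (4, 0), (3, 2)]:
            emp = np.mean((draws[:, 0] == mi) & (draws[:, 1] == li))
            th = pmf[np.searchsorted(m_vals, mi), np.searchsorted(l_vals, li)]
            se = np.sqrt(th * (1 - th) / n)
            assert abs(emp - th) < 4 * se + 1e-12

    def test_truncated_equals_full(self):
        p = params()
        g = 120
        m_f, l_f, full = group_input_distribution(g, p)
        m_t, l_t, trunc = group_input_distribution(g, p, truncate=12.0)
        sub = full[np.ix_(np.isin(m_f, m_t), np.isin(l_f, l_t))]
        assert np.allclose(sub, trunc, atol=1e-15)
        assert trunc.sum() == pytest.approx(1.0, abs=1e-10)


class TestSpikeResponseProbability:
    def test_zero_group(self, ref_theory):
        _, dens, _ = ref_theory
        p, mod = params(), LIN
        assert spike_response_probability(0, p, mod, dens) == 0.0

    def test_degenerate_all_to_all_reduces_to_F(self):
        dens = uniform_density()
        p = params(N=30, p_conn=1.0, p_exc=1.0, eps_inh=-0.0)
        for g in (1, 5, 20):
            expected = excitation_probability(g * p.eps_exc, dens)
            assert spike_response_probability(g, p, LIN, dens) == pytest.approx(
                expected, abs=1e-12
            )

    def test_supra_additive_exceeds_linear(self, ref, ref_theory):
        p, mod = ref
        _, dens, _ = ref_theory
        for g in (100, 150, 200):
            nl = spike_response_probability(g, p, mod, dens)
            li = spike_response_probability(g, p, LIN, dens)
            assert nl > li

    def test_exact_and_truncated_pathways_agree(self, ref, ref_theory):
        p, mod = ref
        _, dens, _ = ref_theory
        g = 310  # just above the default exact-summation switch
        a = spike_response_probability(g, p, mod, dens, g_exact=400)
        b = spike_response_probability(g, p, mod, dens, g_exact=300)
        assert a == pytest.approx(b, rel=1e-10)

    def test_monotone_in_group_size_before_saturation(self, ref, ref_theory):
        p, mod = ref
        _, dens, _ = ref_theory
        ps = [spike_response_probability(g, p, mod, dens) for g in range(0, 201, 25)]
        assert np.all(np.diff(ps) >= -1e-12)


class TestTransitionModel:
    def test_rows_sum_to_one(self, ref_theory):
        _, _, model = ref_theory
        for g in (0, 1, 50, 500, 1999, 2000):
            assert model.transition_pmf(g).sum() == pytest.approx(1.0, abs=1e-12)

    def test_expectation_identities(self, ref_theory):
        _, _, model = ref_theory
        E = model.E_curve
        assert E[model.N] == 0.0
        for g in (10, 100, 400):
            pmf = model.transition_pmf(g)
            mean = np.dot(np.arange(pmf.size), pmf)
            assert mean == pytest.approx(E[g], abs=1e-10)

    def test_zero_response_is_point_mass(self):
        model = TransitionModel(10, np.zeros(11))
        pmf = model.transition_pmf(4)
        assert pmf[0] == 1.0 and pmf.sum() == 1.0

    def test_pmf_matches_bernoulli_enumeration(self):
        """At tiny N the binomial row equals brute-force enumeration over all
        2^(N-g) independent threshold outcomes."""
        N, g, pg = 20, 8, 0.37
        model = TransitionModel(N, np.full(N + 1, pg))
        pmf = model.transition_pmf(g)
        brute = np.zeros(N - g + 1)
        for outcome in itertools.product((0, 1), repeat=N - g):
            k = sum(outcome)
            brute[k] += pg**k * (1 - pg) ** (N - g - k)
        assert np.allclose(pmf, brute, atol=1e-12)

    def test_sampling_mean(self, ref_theory):
        _, _, model = ref_theory
        rng = np.random.default_rng(5)
        g = 150
        draws = model.sample_next(np.full(20_000, g), rng)
        se = np.sqrt(
            (model.N - g) * model.p_of_g[g] * (1 - model.p_of_g[g]) / 20_000
        )
        assert abs(draws.mean() - model.E_curve[g]) < 4 * se
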