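"""End-to-end validation experiments tying simulation and theory together.

Each function runs one self-contained experiment on the calibrated reference
fixtures (or a down-scaled variant) and returns plain numbers, so the same
battery backs both the test suite and the reproduction script.  Problem sizes
are chosen so the whole battery runs in minutes on one core; every experiment
is seeded and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fixtures import linear_ref, nonlinear_ref
from .maps import find_fixed_points
from .model import (
    CouplingMatrix,
    DendriticModulation,
    ModelParams,
    build_network,
    mean_total_input_strengths,
)
from .phase import PhaseFunctions, free_period
from .simulate import (
    SimState,
    SpikeRaster,
    StimulusProtocol,
    advance,
    deliver_wave,
    equilibrate,
    sample_potentials,
    simulate,
)
from .synchrony import background_pulses, extract_chain, parameter_scan
from .theory import (
    build_transition_model,
    empirical_density,
    monte_carlo_transition,
    per_network_response_probability,
    self_consistent_rate,
    stationary_density_diffusion,
)

import scipy.sparse as sp

__all__ = [
    "free_isi_max_relative_error",
    "transition_row_sum_max_deviation",
    "sampled_transition_mean_max_z",
    "wave_response_chi2_pvalues",
    "chain_survival_fractions",
    "TheoryVsMonteCarlo",
    "theory_vs_monte_carlo",
    "scan_dichotomy",
    "absorption_time_z",
    "diffusion_theory",
]


def diffusion_theory(params: ModelParams, mod: DendriticModulation):
    """Self-consistent rate, diffusion density and transition model."""
    nu = self_consistent_rate(params, mod)
    dens = stationary_density_diffusion(params, nu, mod)
    model = build_transition_model(params, mod, dens)
    return nu, dens, model


def free_isi_max_relative_error(seed: int, N: int = 50, duration: float = 8.0) -> float:
    """Max relative deviation of simulated ISIs from the closed-form free
    period in an uncoupled network."""
    params, _ = nonlinear_ref()
    params = params.replace(N=N, eps_exc=0.0, eps_inh=0.0)
    net = CouplingMatrix(sp.csr_matrix((N, N)))
    raster = simulate(params, net, DendriticModulation.identity(), duration,
                      None, seed=seed)
    T = free_period(params)
    worst = 0.0
    for i in range(N):
        t = np.sort(raster.times[raster.ids == i])
        if t.size >= 2:
            worst = max(worst, float(np.max(np.abs(np.diff(t) - T))) / T)
    return worst


def transition_row_sum_max_deviation(N: int = 500) -> float:
    """Max |sum(P(.|g)) - 1| over every group size of an N-neuron model."""
    params, mod = nonlinear_ref()
    _, _, model = diffusion_theory(params.replace(N=N), mod)
    worst = 0.0
    for g in range(N + 1):
        worst = max(worst, abs(float(model.transition_pmf(g).sum()) - 1.0))
    return worst


def sampled_transition_mean_max_z(
    seed: int, g_values=(10, 100, 300), n_samples: int = 100_000
) -> tuple[float, float]:
    """Check the binomial identity E(g) = sum g' P(g'|g) and compare the mean
    of sampled transitions with E(g).

    Returns (max |E - pmf mean|, max |z| of the sampled means in SE units).
    """
    params, mod = nonlinear_ref()
    _, _, model = diffusion_theory(params, mod)
    rng = np.random.default_rng(seed)
    max_ident = 0.0
    max_z = 0.0
    for g in g_values:
        pmf = model.transition_pmf(g)
        mean_pmf = float(np.dot(np.arange(pmf.size), pmf))
        max_ident = max(max_ident, abs(mean_pmf - model.E_curve[g]))
        n, p = model.N - g, model.p_of_g[g]
        draws = rng.binomial(n, p, size=n_samples)
        se = np.sqrt(n * p * (1 - p) / n_samples)
        max_z = max(max_z, abs(draws.mean() - model.E_curve[g]) / se)
    return max_ident, max_z


def _chi2_vs_binomial(counts: np.ndarray, n: int, p: float) -> float:
    """Goodness-of-fit p-value of observed response counts against
    Binomial(n, p), with bins merged to expected counts >= 5."""
    n_trials = counts.size
    kmax = int(counts.max())
    k = np.arange(0, max(kmax + 1, 2))
    expected = stats.binom.pmf(k, n, p) * n_trials
    # everything beyond the observed range goes into the final open bin
    expected[-1] += stats.binom.sf(k[-1], n, p) * n_trials
    observed = np.bincount(counts, minlength=k.size).astype(float)
    # merge adjacent bins until every expected count reaches 5
    obs_b, exp_b = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(observed, expected):
        o_acc += o
        e_acc += e
        if e_acc >= 5.0:
            obs_b.append(o_acc)
            exp_b.append(e_acc)
            o_acc = e_acc = 0.0
    if obs_b:
        obs_b[-1] += o_acc
        exp_b[-1] += e_acc
    obs_b, exp_b = np.array(obs_b), np.array(exp_b)
    exp_b *= obs_b.sum() / exp_b.sum()
    if obs_b.size < 2:
        return 1.0
    return float(stats.chisquare(obs_b, exp_b).pvalue)


def wave_response_chi2_pvalues(
    seed: int,
    g_values=(10, 50, 100),
    N: int = 200,
    n_trials: int = 2000,
) -> dict[int, float]:
    """Single-wave oracle: on a frozen network with potentials drawn i.i.d.
    from the stationary density, firing counts in response to a synchronous
    pulse of g random senders must follow Binomial(N - g, p_hat(g)) with
    p_hat obtained by exact per-neuron enumeration.

    Returns the chi-square goodness-of-fit p-value per group size.
    """
    params, mod = nonlinear_ref()
    params = params.replace(N=N)
    pf = PhaseFunctions.from_params(params)
    ss = np.random.SeedSequence(seed)
    net_seed, sim_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    matrix = build_network(params, net_seed)
    nu = self_consistent_rate(params, mod)
    dens = stationary_density_diffusion(params, nu, mod)
    rng = np.random.default_rng(sim_seed)
    out: dict[int, float] = {}
    for g in g_values:
        p_hat = per_network_response_probability(matrix, params, mod, dens, g)
        counts = np.empty(n_trials, dtype=np.int64)
        for t in range(n_trials):
            V = dens.sample(N, rng)
            state = SimState(
                0.0,
                pf.phi_theta - pf.U_inv(V),
                np.empty(0),
                np.empty(0, np.int64),
                rng_seed=sim_seed,
            )
            senders = rng.choice(N, size=g, replace=False)
            fired = deliver_wave(state, senders, matrix, mod, pf)
            counts[t] = np.setdiff1d(fired, senders).size
        out[g] = _chi2_vs_binomial(counts, N - g, p_hat)
    return out


def _one_chain_run(
    params: ModelParams,
    mod: DendriticModulation,
    g0: int,
    seed: int,
    steps: int,
    t_eq: float = 10.0,
    pre_window: float = 5.0,
    post_window: float = 2.0,
):
    """Equilibrate, observe background, stimulate g0, follow the chain.

    Returns (chain sizes over `steps`, largest background pulse)."""
    ss = np.random.SeedSequence(seed)
    s_net, s_eq, s_stim = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    matrix = build_network(params, s_net)
    state = equilibrate(params, matrix, mod, t_eq, seed=s_eq)
    pre, state = advance(state, params, matrix, mod, pre_window)
    t0 = state.t_now
    stim = StimulusProtocol.single(t0, g0, params.N, seed=s_stim)
    span = (steps + 1) * params.tau + post_window
    post, _ = advance(state, params, matrix, mod, span, stim=stim)
    raster = SpikeRaster.concat([pre, post])
    horizon = int(np.ceil(span / params.tau)) + 1
    chain = extract_chain(raster, t0, params.tau, horizon)
    bg_pre = background_pulses(raster, chain, (t0 - pre_window, t0))
    bg_post = background_pulses(raster, chain, (t0, t0 + span))
    sizes = chain.sizes[: steps + 1]
    return sizes, max(bg_pre.max_size, bg_post.max_size)


def chain_survival_fractions(
    seed: int, n_seeds: int = 20, die_steps: int = 20, survive_steps: int = 50
) -> dict[str, float]:
    """Linear/nonlinear dichotomy on the calibrated fixtures.

    * linear_ref, g0 = 100: fraction of runs whose chain reaches size 0
      within ``die_steps`` steps;
    * nonlinear_ref, g0 in the middle of (psi_zero, psi_plus]: fraction of
      runs whose first ``survive_steps`` groups all exceed the largest
      background pulse of the same run.
    """
    params_l, mod_l = linear_ref()
    params_n, mod_n = nonlinear_ref()
    _, _, model = diffusion_theory(params_n, mod_n)
    fps = find_fixed_points(model.E_curve)
    g0_n = int(round(0.5 * (fps.psi_zero + fps.psi_plus)))
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2 * n_seeds)]

    died = 0
    for s in seeds[:n_seeds]:
        sizes, _ = _one_chain_run(params_l, mod_l, 100, s, steps=die_steps)
        if np.any(sizes[: die_steps + 1] == 0):
            died += 1

    survived = 0
    for s in seeds[n_seeds:]:
        sizes, bg_max = _one_chain_run(params_n, mod_n, g0_n, s, steps=survive_steps)
        alive = sizes.size >= survive_steps + 1 and np.all(
            sizes[1 : survive_steps + 1] > bg_max
        )
        survived += bool(alive)

    return {
        "linear_die_fraction": died / n_seeds,
        "nonlinear_survive_fraction": survived / n_seeds,
        "g0_nonlinear": g0_n,
    }


@dataclass
class TheoryVsMonteCarlo:
    g_values: np.ndarray
    mc_means: np.ndarray
    E_semi: np.ndarray  # semi-analytic expectation at g_values
    sd_semi: np.ndarray  # binomial SD of the semi-analytic model
    n_within_band: int
    max_rel_dev_curves: float  # diffusion vs semi-analytic, over E >= 5
    psi_semi: tuple
    psi_diff: tuple


def theory_vs_monte_carlo(
    seed: int,
    g_values=(50, 100, 150, 200, 250, 300, 400, 500),
    n_networks: int = 3,
    trials_per_network: int = 8,
    t_eq: float = 10.0,
    n_snapshots: int = 80,
) -> TheoryVsMonteCarlo:
    """Single-step transition means measured in full simulations versus the
    Markov theory, plus the deviation between the diffusion and semi-analytic
    expectation curves.
    """
    params, mod = nonlinear_ref()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_networks)
    snaps = []
    samples = {g: [] for g in g_values}
    for child in children:
        s_net, s_eq, s_mc = (int(s.generate_state(1)[0] % 2**31) for s in child.spawn(3))
        matrix = build_network(params, s_net)
        state = equilibrate(params, matrix, mod, t_eq, seed=s_eq)
        pot, state = sample_potentials(
            state, params, matrix, mod, n_snapshots, interval=0.31
        )
        snaps.append(pot.ravel())
        for k, g in enumerate(g_values):
            mc = monte_carlo_transition(
                params, matrix, mod, g, trials_per_network,
                seed=s_mc + k, state=state.copy(),
            )
            samples[g].append(mc.samples)

    dens_emp = empirical_density(np.concatenate(snaps), params)
    model_semi = build_transition_model(params, mod, dens_emp)
    _, _, model_diff = diffusion_theory(params, mod)

    g_arr = np.asarray(g_values)
    mc_means = np.array([np.concatenate(samples[g]).mean() for g in g_values])
    E_semi = model_semi.E_curve[g_arr]
    p = model_semi.p_of_g[g_arr]
    sd_semi = np.sqrt((params.N - g_arr) * p * (1 - p))
    within = int(np.sum(np.abs(mc_means - E_semi) <= 2 * sd_semi))

    E_d, E_e = model_diff.E_curve, model_semi.E_curve
    mask = E_e >= 5
    max_rel = float(np.max(np.abs(E_d[mask] - E_e[mask]) / E_e[mask]))
    fps_e = find_fixed_points(E_e)
    fps_d = find_fixed_points(E_d)
    return TheoryVsMonteCarlo(
        g_values=g_arr,
        mc_means=mc_means,
        E_semi=E_semi,
        sd_semi=sd_semi,
        n_within_band=within,
        max_rel_dev_curves=max_rel,
        psi_semi=(fps_e.psi_minus, fps_e.psi_zero, fps_e.psi_plus),
        psi_diff=(fps_d.psi_minus, fps_d.psi_zero, fps_d.psi_plus),
    )


def _largest_stable_component(table) -> int:
    """Size of the largest 4-connected block of stable cells in a scan table."""
    E_vals = sorted(table["E_tot"].unique())
    I_vals = sorted(table["I_tot"].unique())
    stable = {
        (row["E_tot"], row["I_tot"])
        for _, row in table.iterrows()
        if row["label"] == "stable_propagation"
    }
    best = 0
    seen = set()
    for cell in stable:
        if cell in seen:
            continue
        stack, comp = [cell], 0
        seen.add(cell)
        while stack:
            e, i = stack.pop()
            comp += 1
            ei, ii = E_vals.index(e), I_vals.index(i)
            for de, di in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ne, ni = ei + de, ii + di
                if 0 <= ne < len(E_vals) and 0 <= ni < len(I_vals):
                    nb = (E_vals[ne], I_vals[ni])
                    if nb in stable and nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
        best = max(best, comp)
    return best


def scan_dichotomy(
    seed: int,
    n_nets: int = 3,
    rel_grid=(0.8, 0.9, 1.0, 1.1, 1.2),
    g0: int = 100,
    **protocol_kwargs,
):
    """5 x 5 coupling-strength scans around the reference point, for the
    nonlinear and the linear network.

    Returns (nonlinear table, linear table, largest stable block size in the
    nonlinear scan, number of stable cells in the linear scan).
    """
    params, mod = nonlinear_ref()
    E0, I0 = mean_total_input_strengths(params)
    E_grid = [E0 * f for f in rel_grid]
    I_grid = [I0 * f for f in rel_grid]
    kw = dict(t_eq=6.0, pre_window=4.0, post_window=2.0, K_min=15, horizon=20)
    kw.update(protocol_kwargs)
    tab_nl = parameter_scan(params, mod, E_grid, I_grid, g0=g0,
                            n_nets=n_nets, seed=seed, **kw)
    tab_lin = parameter_scan(params, DendriticModulation.identity(), E_grid,
                             I_grid, g0=g0, n_nets=n_nets, seed=seed, **kw)
    block = _largest_stable_component(tab_nl)
    n_lin_stable = int((tab_lin["label"] == "stable_propagation").sum())
    return tab_nl, tab_lin, block, n_lin_stable


def absorption_time_z(seed: int, N: int = 50, g0: int = 30,
                      n_chains: int = 4000) -> tuple[float, float, float]:
    """Mean absorption time of a strictly subcritical group-size chain:
    Monte-Carlo versus the exact fundamental-matrix value.

    Uses p(g) = min(0.5 g / (N - g), 0.95), for which E(g) < g at every
    g > 0.  Returns (MC mean, exact mean, |z| in SE units).
    """
    from .maps import expected_absorption_time, mc_absorption_time
    from .theory import TransitionModel

    g = np.arange(N + 1)
    p = np.minimum(0.5 * g / np.maximum(N - g, 1), 0.95)
    p[0] = 0.0
    model = TransitionModel(N, p)
    assert np.all(model.E_curve[1:] < g[1:])
    exact = expected_absorption_time(model, g0)
    times = mc_absorption_time(model, g0, n_chains=n_chains, seed=seed)
    se = times.std(ddof=1) / np.sqrt(n_chains)
    return float(times.mean()), float(exact), float(abs(times.mean() - exact) / se)
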