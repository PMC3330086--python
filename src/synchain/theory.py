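"""Markov-chain theory of synchronous-group propagation.

The chain of synchronous pulses is modelled as a Markov process on the group
size g.  Under the assumptions that (a) the sequence of group sizes is
Markovian, (b) propagation leaves the background statistics unchanged, and
(c) the neurons that spiked in the previous pulse are refractory while all
others are equilibrated, the next group size given a current size g is

    P(g' | g) = Binomial(g'; N - g, p(g)),                       (transition)
    E(g)      = (N - g) * p(g),                                  (expectation)

where p(g) is the probability that an equilibrated neuron spikes in response
to a synchronous pulse of g spikes:

    p(g) = sum_{m,l} P(m, l | g) * F( sigma(m*eps_exc) + l*eps_inh ).

Here (m, l) — the numbers of excitatory/inhibitory inputs the neuron receives
from the g senders — is trinomial with per-sender link probabilities
(p_conn*p_exc, p_conn*p_inh), and F(lam) is the probability that an input of
total strength lam lifts the membrane potential above threshold,

    F(lam) = integral from V_theta - lam to V_theta of P(V) dV   (lam > 0),

the right cumulative of the stationary membrane-potential density P(V).
P(V) is obtained either analytically — diffusion approximation of the
Poissonian background bombardment, i.e. the stationary Fokker-Planck solution
of the LIF with absorbing threshold and reset re-injection, with the
self-consistent rate from the Siegert formula — or semi-analytically from
membrane-potential histograms measured in simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, special, stats

from .model import (
    CouplingMatrix,
    DendriticModulation,
    ModelParams,
    sigma_modulate,
)
from .phase import PhaseFunctions, free_period
from .simulate import StimulusProtocol, SimulationUnstable, advance, equilibrate

__all__ = [
    "StationaryDensity",
    "TransitionModel",
    "siegert_rate",
    "self_consistent_rate",
    "stationary_density_diffusion",
    "empirical_density",
    "excitation_probability",
    "group_input_distribution",
    "spike_response_probability",
    "build_transition_model",
    "per_network_response_probability",
    "MonteCarloTransitions",
    "monte_carlo_transition",
    "background_drift_diffusion",
]


# --------------------------------------------------------------------------
# stationary membrane-potential statistics
# --------------------------------------------------------------------------


@dataclass
class StationaryDensity:
    """Stationary membrane-potential density on an ordered potential grid."""

    grid: np.ndarray
    density: np.ndarray
    rate_nu: float
    source: str  # "diffusion" or "empirical"
    V_theta: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        # right-cumulative R(V) = integral_V^{V_theta} P du, by trapezoid
        total = np.trapezoid(self.density, self.grid)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"density not normalized: integral = {total}")
        left = integrate.cumulative_trapezoid(
            self.density, self.grid, initial=0.0
        )
        self._right_cum = total - left

    @property
    def V_low(self) -> float:
        return float(self.grid[0])

    def right_cumulative(self, V):
        """Probability mass above potential V (clipped to [0, 1])."""
        r = np.interp(V, self.grid, self._right_cum, left=self._right_cum[0], right=0.0)
        return np.clip(r, 0.0, 1.0)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n potentials by inverse-CDF sampling on the grid."""
        cdf = integrate.cumulative_trapezoid(self.density, self.grid, initial=0.0)
        cdf /= cdf[-1]
        return np.interp(rng.random(n), cdf, self.grid)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"V": self.grid, "density": self.density})


def background_drift_diffusion(
    params: ModelParams, mod: DendriticModulation, nu: float
) -> tuple[float, float]:
    """Drift mu (potential/time) and diffusion sigma_w^2 (potential^2/time)
    of the white-noise reduction of the background input at network rate nu.

    Background spikes arrive asynchronously, so a single EPSP passes through
    sigma on its own: its effective amplitude is sigma(eps_exc).
    """
    eff_exc = sigma_modulate(params.eps_exc, mod)
    k = nu * params.N * params.p_conn
    mu = params.I_ext + k * (
        params.p_exc * eff_exc + params.p_inh * params.eps_inh
    )
    sig2 = k * (params.p_exc * eff_exc**2 + params.p_inh * params.eps_inh**2)
    return mu, sig2


def siegert_rate(params: ModelParams, mu: float, sigma_w2: float) -> float:
    """Stationary firing rate of a LIF neuron with white-noise input.

    Input: drift mu (potential/time) and diffusion sigma_w^2
    (potential^2/time); leak gamma, threshold V_theta, reset V_reset.
    1/nu = (sqrt(pi)/gamma) * int_{z_r}^{z_theta} erfcx(-z) dz with
    z = (V - mu/gamma) / (sigma_w / sqrt(gamma)).
    """
    g = params.gamma
    if sigma_w2 <= 0:
        # noiseless limit: deterministic supra- or sub-threshold drive
        mean = mu / g
        if mean <= params.V_theta:
            return 0.0
        return g / np.log((mean - params.V_reset) / (mean - params.V_theta))
    sig_eff = np.sqrt(sigma_w2 / g)
    z_r = (params.V_reset - mu / g) / sig_eff
    z_t = (params.V_theta - mu / g) / sig_eff
    val, _ = integrate.quad(
        lambda z: special.erfcx(-z), z_r, z_t, epsrel=1e-10, limit=200
    )
    return g / (np.sqrt(np.pi) * val)


def self_consistent_rate(
    params: ModelParams,
    mod: DendriticModulation,
    rate_cap: float | None = None,
    rtol: float = 1e-8,
) -> float:
    """Solve nu = SiegertRate(mu(nu), sigma_w^2(nu)) for the background rate.

    Root found by bracketing + Brent's method to relative tolerance rtol.
    """
    if params.eps_exc == 0 and params.eps_inh == 0:
        return 1.0 / free_period(params)
    if rate_cap is None:
        rate_cap = 25.0 / free_period(params)

    def f(nu: float) -> float:
        mu, s2 = background_drift_diffusion(params, mod, nu)
        return siegert_rate(params, mu, s2) - nu

    lo, hi = 0.0, rate_cap
    if f(lo) < 0:
        raise RuntimeError("no self-consistent rate: map below identity at 0")
    if f(hi) > 0:
        raise RuntimeError(
            f"no self-consistent rate in bracket [0, {rate_cap:.4g}]: "
            "rate map exceeds the cap (runaway excitation?)"
        )
    nu = optimize.brentq(f, lo, hi, rtol=rtol)
    return float(nu)


def _standard_grid(
    params: ModelParams, sig_eff: float, n_points: int = 2001
) -> np.ndarray:
    span = 10.0 * max(sig_eff, params.V_theta - params.V_reset)
    return np.linspace(params.V_theta - span, params.V_theta, n_points)


def stationary_density_diffusion(
    params: ModelParams,
    rate_nu: float,
    mod: DendriticModulation | None = None,
    n_points: int = 2001,
) -> StationaryDensity:
    """Stationary Fokker-Planck density of the LIF driven by white noise.

    Absorbing boundary at V_theta (density vanishes there) with re-injection
    of the outflux at V_reset.  For sigma_w = 0 the degenerate branch is the
    deterministic-flow occupancy 1/(T_free * (I_ext - gamma V)) on
    (V_reset, V_theta).
    """
    if mod is None:
        mod = DendriticModulation.identity()
    mu, s2 = background_drift_diffusion(params, mod, rate_nu)
    g = params.gamma
    if s2 <= 0:
        # deterministic flow: all mass sits on [V_reset, V_theta], so the
        # grid covers exactly that support (no boundary-layer padding needed)
        grid = np.linspace(params.V_reset, params.V_theta, n_points)
        T = free_period(params)
        dens = 1.0 / (T * (params.I_ext - g * grid))
        dens /= np.trapezoid(dens, grid)
        return StationaryDensity(grid, dens, rate_nu, "diffusion", params.V_theta)

    sig_eff = np.sqrt(s2 / g)
    grid = _standard_grid(params, sig_eff, n_points)
    z = (grid - mu / g) / sig_eff
    z_t = (params.V_theta - mu / g) / sig_eff
    z_r = (params.V_reset - mu / g) / sig_eff
    z_hi = np.maximum(z, z_r)
    # exp(-z^2) * int_{z_hi}^{z_t} exp(u^2) du, via the Dawson function:
    # int_0^x e^{u^2} du = e^{x^2} D(x); exponent differences keep it stable.
    e1 = np.clip(z_t**2 - z**2, None, 700.0)
    e2 = np.clip(z_hi**2 - z**2, None, 700.0)
    shape = np.exp(e1) * special.dawsn(z_t) - np.exp(e2) * special.dawsn(z_hi)
    shape = np.clip(shape, 0.0, None)
    shape[-1] = 0.0  # absorbing boundary, exact
    norm = np.trapezoid(shape, grid)
    return StationaryDensity(
        grid, shape / norm, rate_nu, "diffusion", params.V_theta
    )


def empirical_density(
    snapshots: np.ndarray,
    params: ModelParams,
    rate_nu: float = np.nan,
    n_bins: int = 400,
) -> StationaryDensity:
    """Normalized histogram of measured membrane potentials.

    This is the semi-analytic pathway: it bypasses the diffusion and
    mean-connectivity approximations by measuring P(V) directly in the
    simulated background activity.
    """
    v = np.asarray(snapshots, dtype=float).ravel()
    if v.size < 10_000:
        warnings.warn(
            f"only {v.size} potential samples: excitation probabilities "
            "will be noisy",
            RuntimeWarning,
            stacklevel=2,
        )
    lo = min(float(v.min()), params.V_theta - (params.V_theta - params.V_reset))
    edges = np.linspace(lo, params.V_theta, n_bins + 1)
    hist, _ = np.histogram(v, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dens = hist / (v.size * (edges[1] - edges[0]))
    norm = np.trapezoid(dens, centers)
    return StationaryDensity(
        centers, dens / norm, rate_nu, "empirical", params.V_theta
    )


def excitation_probability(lam, dens: StationaryDensity):
    """F(lam): probability that an input of strength lam crosses threshold.

    F(lam) = int_{V_theta - lam}^{V_theta} P(V) dV for lam > 0 and 0 for
    lam <= 0; non-decreasing, saturating at 1.
    """
    lam_arr = np.asarray(lam, dtype=float)
    F = np.where(
        lam_arr > 0, dens.right_cumulative(dens.V_theta - lam_arr), 0.0
    )
    if np.ndim(lam) == 0:
        return float(F)
    return F


# --------------------------------------------------------------------------
# group-size transition model
# --------------------------------------------------------------------------


def group_input_distribution(
    g: int, params: ModelParams, truncate: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint pmf of the numbers (m, l) of excitatory and inhibitory inputs a
    neuron receives from a synchronous group of g senders.

    (m, l) is trinomial with g trials and per-sender cell probabilities
    (p_conn*p_exc, p_conn*p_inh, 1 - p_conn).  Returns (m_values, l_values,
    pmf[m, l]).  ``truncate`` restricts each marginal's support to its
    [q, 1-q] quantile range with q = 10^-truncate; the omitted joint tail
    mass is below ~1e-12 at the default used for large groups.
    """
    if not 0 <= g <= params.N:
        raise ValueError("g must lie in [0, N]")
    q_e = params.p_conn * params.p_exc
    q_i = params.p_conn * params.p_inh
    if g == 0:
        return np.array([0]), np.array([0]), np.array([[1.0]])
    if truncate is None:
        m_vals = np.arange(g + 1)
        l_vals = np.arange(g + 1)
    else:
        tail = 10.0 ** (-truncate)

        def bulk(q):
            lo = max(0, int(stats.binom.ppf(tail, g, q)) - 1)
            hi = min(g, int(stats.binom.isf(tail, g, q)) + 1)
            return np.arange(lo, hi + 1)

        m_vals, l_vals = bulk(q_e), bulk(q_i)
    pm = stats.binom.pmf(m_vals, g, q_e)
    q_cond = q_i / (1.0 - q_e) if q_e < 1 else (1.0 if q_i > 0 else 0.0)
    n_rem = (g - m_vals)[:, None]
    pl = stats.binom.pmf(l_vals[None, :], np.maximum(n_rem, 0), q_cond)
    pl[(l_vals[None, :] > n_rem)] = 0.0
    pmf = pm[:, None] * pl
    return m_vals, l_vals, pmf


def spike_response_probability(
    g: int,
    params: ModelParams,
    mod: DendriticModulation,
    dens: StationaryDensity,
    g_exact: int = 300,
) -> float:
    """p(g): probability that an equilibrated neuron spikes in response to a
    synchronous pulse of g spikes.

    Exact trinomial summation for g <= g_exact; for larger g the summation is
    restricted to the 1e-12 quantile bulk of the input-count marginals, which
    keeps the evaluation exact to ~1e-11 at any N for the same cost.
    """
    truncate = None if g <= g_exact else 12.0
    m_vals, l_vals, pmf = group_input_distribution(g, params, truncate)
    lam = (
        sigma_modulate(m_vals * params.eps_exc, mod)[:, None]
        + l_vals[None, :] * params.eps_inh
    )
    F = excitation_probability(lam, dens)
    return float(np.sum(pmf * F))


@dataclass
class TransitionModel:
    """Binomial group-size transition model on states g = 0 .. N.

    ``p_of_g[g]`` is the response probability of each of the N - g available
    (non-refractory) neurons; the expectation curve is E(g) = (N-g)*p_of_g[g].
    """

    N: int
    p_of_g: np.ndarray

    def __post_init__(self) -> None:
        self.p_of_g = np.asarray(self.p_of_g, dtype=float)
        if self.p_of_g.shape != (self.N + 1,):
            raise ValueError("p_of_g must have length N + 1")
        if np.any((self.p_of_g < 0) | (self.p_of_g > 1)):
            raise ValueError("p_of_g values must lie in [0, 1]")

    @property
    def E_curve(self) -> np.ndarray:
        g = np.arange(self.N + 1)
        return (self.N - g) * self.p_of_g

    def transition_pmf(self, g: int) -> np.ndarray:
        """P(g' | g) over g' = 0 .. N - g (binomial row; sums to 1)."""
        n = self.N - g
        return stats.binom.pmf(np.arange(n + 1), n, self.p_of_g[g])

    def sample_next(self, g, rng: np.random.Generator):
        g = np.asarray(g)
        return rng.binomial(self.N - g, self.p_of_g[g])

    def to_frame(self):
        import pandas as pd

        g = np.arange(self.N + 1)
        return pd.DataFrame(
            {"g": g, "p_g": self.p_of_g, "E_hat": self.E_curve}
        )

    def pmf_frame(self, threshold: float = 1e-12):
        """Sparse long-format pmf table (g, g_prime, prob >= threshold)."""
        import pandas as pd

        rows = []
        for g in range(self.N + 1):
            pmf = self.transition_pmf(g)
            keep = np.flatnonzero(pmf >= threshold)
            rows.append(
                pd.DataFrame(
                    {"g": g, "g_prime": keep, "prob": pmf[keep]}
                )
            )
        return pd.concat(rows, ignore_index=True)


def build_transition_model(
    params: ModelParams,
    mod: DendriticModulation,
    dens: StationaryDensity,
    g_exact: int = 300,
) -> TransitionModel:
    """Evaluate p(g) for all g = 0 .. N and assemble the transition model."""
    p = np.array(
        [
            spike_response_probability(g, params, mod, dens, g_exact=g_exact)
            for g in range(params.N + 1)
        ]
    )
    return TransitionModel(params.N, np.clip(p, 0.0, 1.0))


# --------------------------------------------------------------------------
# per-network oracle and Monte-Carlo validation
# --------------------------------------------------------------------------


def per_network_response_probability(
    matrix: CouplingMatrix,
    params: ModelParams,
    mod: DendriticModulation,
    dens: StationaryDensity,
    g: int,
) -> float:
    """Exact response probability for one frozen network.

    For a uniformly random g-subset of senders, the numbers (m, l) of
    excitatory/inhibitory inputs a non-sender neuron i receives are jointly
    hypergeometric in its realized in-degree composition (k_e, k_i).  The
    returned value is the average over neurons of
    sum_{m,l} P_hyp(m, l) F(sigma(m*eps_exc) + l*eps_inh).
    """
    N = params.N
    coo = matrix.csr.tocoo()
    k_e = np.bincount(coo.col[coo.data > 0], minlength=N)
    k_i = np.bincount(coo.col[coo.data < 0], minlength=N)
    probs = np.empty(N)
    cache: dict[tuple[int, int], float] = {}
    for i in range(N):
        key = (int(k_e[i]), int(k_i[i]))
        if key not in cache:
            ke, ki = key
            m_vals = np.arange(0, min(ke, g) + 1)
            pm = stats.hypergeom.pmf(m_vals, N - 1, ke, g)
            q = 0.0
            for m, w in zip(m_vals, pm):
                if w < 1e-16:
                    continue
                l_vals = np.arange(0, min(ki, g - m) + 1)
                pl = stats.hypergeom.pmf(l_vals, N - 1 - ke, ki, g - m)
                lam = (
                    sigma_modulate(m * params.eps_exc, mod)
                    + l_vals * params.eps_inh
                )
                q += w * np.sum(pl * excitation_probability(lam, dens))
            cache[key] = q
        probs[i] = cache[key]
    return float(probs.mean())


@dataclass
class MonteCarloTransitions:
    """Empirical single-step transitions g -> g1 measured in simulation."""

    g: int
    samples: np.ndarray
    n_aborts: int

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def frequencies(self):
        import pandas as pd

        vals, counts = np.unique(self.samples, return_counts=True)
        return pd.Series(counts / self.samples.size, index=vals, name="freq")


def monte_carlo_transition(
    params: ModelParams,
    matrix: CouplingMatrix,
    mod: DendriticModulation,
    g: int,
    n_trials: int,
    seed: int,
    t_eq: float = 10.0,
    decorrelate: float = 1.5,
    state=None,
) -> MonteCarloTransitions:
    """Measure the empirical distribution of g1 after stimulating g neurons.

    The background is equilibrated once (or taken from ``state``); each trial
    stimulates a fresh uniformly random g-subset on a snapshot of the running
    background, measures the pulse size one delay later, restores the
    snapshot and advances the background by ``decorrelate`` time units.
    """
    ss = np.random.SeedSequence(seed)
    eq_seed, pick_seed = ss.spawn(2)
    rng = np.random.default_rng(pick_seed)
    if state is None:
        state = equilibrate(
            params, matrix, mod, t_eq, seed=int(eq_seed.generate_state(1)[0] % 2**31)
        )
    tau = params.tau
    tol = 1e-9 * tau
    samples = np.empty(n_trials, dtype=np.int64)
    n_aborts = 0
    k = 0
    while k < n_trials:
        t0 = state.t_now
        if g > 0:
            ids = rng.choice(params.N, size=g, replace=False).astype(np.int64)
            stim = StimulusProtocol([(t0, ids)])
        else:
            stim = None
        try:
            raster, _ = advance(
                state, params, matrix, mod, 1.5 * tau, stim=stim
            )
            g1 = int(
                np.count_nonzero(np.abs(raster.times - (t0 + tau)) <= tol)
            )
            samples[k] = g1
            k += 1
        except SimulationUnstable:
            n_aborts += 1
            if n_aborts > 10 * n_trials:
                raise
        # advance the untouched background to decorrelate trials
        _, state = advance(state, params, matrix, mod, decorrelate)
    return MonteCarloTransitions(g, samples[:k], n_aborts)
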