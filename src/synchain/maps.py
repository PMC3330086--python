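"""Fixed points and iteration of the group-size map.

The expectation curve E(g) = (N-g) p(g), interpolated piecewise-linearly
between integer group sizes, defines a one-dimensional map for the evolution
of synchronous-pulse sizes.  Its intersections with the diagonal are the
fixed points: g = 0 is always absorbing; a map with a single small stable
point describes decaying synchrony (linear coupling), while supra-additive
coupling can create a second stable point psi_plus above an unstable
threshold psi_zero — the signature of persistent propagation.  The stochastic
counterpart iterates the full binomial transition kernel.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .model import DendriticModulation, ModelParams
from .theory import (
    StationaryDensity,
    TransitionModel,
    build_transition_model,
    self_consistent_rate,
    stationary_density_diffusion,
)

__all__ = [
    "FixedPoint",
    "FixedPointSet",
    "find_fixed_points",
    "interp_curve",
    "IterationResult",
    "iterate_deterministic",
    "iterate_stochastic",
    "transition_matrix",
    "expected_absorption_time",
    "mc_absorption_time",
    "CalibrationReport",
    "calibrate_fixtures",
]


@dataclass(frozen=True)
class FixedPoint:
    g: float
    stability: str  # "stable" | "unstable" | "marginal"
    slope: float


@dataclass
class FixedPointSet:
    """Fixed points of the interpolated expectation curve, in ascending order."""

    points: list[FixedPoint]
    psi_minus: float | None = None
    psi_zero: float | None = None
    psi_plus: float | None = None

    @property
    def bistable(self) -> bool:
        return (
            self.psi_minus is not None
            and self.psi_zero is not None
            and self.psi_plus is not None
        )

    def to_dict(self) -> dict:
        return {
            "points": [
                {"g": p.g, "stability": p.stability, "slope": p.slope}
                for p in self.points
            ],
            "psi_minus": self.psi_minus,
            "psi_zero": self.psi_zero,
            "psi_plus": self.psi_plus,
        }


def interp_curve(E_curve: np.ndarray):
    """Piecewise-linear interpolant of E on integer group sizes."""
    E = np.asarray(E_curve, dtype=float)
    grid = np.arange(E.size)

    def f(g):
        return np.interp(g, grid, E)

    return f


def find_fixed_points(E_curve: np.ndarray, slope_tol: float = 1e-9) -> FixedPointSet:
    """Locate intersections of the interpolated expectation curve with the
    diagonal and classify their stability by the interpolated slope.

    |dE/dg| < 1 is stable, > 1 unstable; a slope within ``slope_tol`` of 1 in
    magnitude is flagged marginal.  g = 0 is always reported (absorbing).
    """
    E = np.asarray(E_curve, dtype=float)
    n = E.size - 1
    D = E - np.arange(E.size)  # sign changes of E(g) - g
    points: list[FixedPoint] = []

    def classify(slope: float) -> str:
        if abs(abs(slope) - 1.0) <= slope_tol:
            return "marginal"
        return "stable" if abs(slope) < 1.0 else "unstable"

    def add(g_star: float, slope: float) -> None:
        if points and abs(points[-1].g - g_star) < 1e-9 * max(n, 1):
            return
        points.append(FixedPoint(float(g_star), classify(slope), float(slope)))

    # absorbing fixed point at zero, classified by the first segment's slope
    add(0.0, E[1] - E[0] if n >= 1 else 0.0)
    for k in range(n):
        slope = E[k + 1] - E[k]
        if D[k] == 0.0 and k > 0:
            add(float(k), slope)
        if D[k] * D[k + 1] < 0.0:
            # root of the linear segment: k + D[k] / (D[k] - D[k+1])
            g_star = k + D[k] / (D[k] - D[k + 1])
            add(g_star, slope)
    if n >= 1 and D[n] == 0.0 and n > 0:
        add(float(n), E[n] - E[n - 1])

    fps = FixedPointSet(points)
    stable = [p.g for p in points if p.stability == "stable"]
    unstable = [p.g for p in points if p.stability == "unstable"]
    for u in sorted(unstable):
        below = [s for s in stable if s < u]
        above = [s for s in stable if s > u]
        if below and above:
            fps.psi_zero = u
            fps.psi_minus = max(below)
            fps.psi_plus = min(above)
            break
    return fps


@dataclass
class IterationResult:
    """Deterministic orbit of the rounded expectation map."""

    sizes: np.ndarray
    period: int | None = None  # detected terminal period (1 = fixed point)

    def __iter__(self):
        return iter(self.sizes)


def iterate_deterministic(
    E_curve: np.ndarray, g0: int, K: int, max_period: int = 8
) -> IterationResult:
    """Iterate g_{k+1} = round(E_interp(g_k)) for K steps (round half up).

    Detects convergence onto a fixed point or a periodic orbit of period up
    to ``max_period`` (two full cycles at the tail are required).
    """
    E = np.asarray(E_curve, dtype=float)
    N = E.size - 1
    if not 0 <= g0 <= N:
        raise ValueError("g0 must lie in [0, N]")
    f = interp_curve(E)
    sizes = np.empty(K + 1, dtype=np.int64)
    sizes[0] = g0
    for k in range(K):
        sizes[k + 1] = int(np.floor(f(sizes[k]) + 0.5))
    period = None
    for p in range(1, max_period + 1):
        if K + 1 >= 2 * p + 1 and np.all(sizes[-p:] == sizes[-2 * p : -p]):
            period = p
            break
    return IterationResult(sizes, period)


def iterate_stochastic(
    model: TransitionModel, g0: int, K: int, seed: int
) -> np.ndarray:
    """Sample a chain g_0 .. g_K from the binomial transition kernel.

    The state 0 is absorbing.  Reproducible given ``seed``.
    """
    if not 0 <= g0 <= model.N:
        raise ValueError("g0 must lie in [0, N]")
    rng = np.random.default_rng(seed)
    sizes = np.empty(K + 1, dtype=np.int64)
    sizes[0] = g0
    g = g0
    for k in range(K):
        if g == 0:
            sizes[k + 1 :] = 0
            return sizes
        g = int(rng.binomial(model.N - g, model.p_of_g[g]))
        sizes[k + 1] = g
    return sizes


def transition_matrix(model: TransitionModel) -> np.ndarray:
    """Dense (N+1) x (N+1) transition matrix W[g, g'] of the group-size chain."""
    N = model.N
    W = np.zeros((N + 1, N + 1))
    for g in range(N + 1):
        pmf = model.transition_pmf(g)
        W[g, : pmf.size] = pmf
    return W


def expected_absorption_time(model: TransitionModel, g0: int) -> float:
    """Exact mean number of steps to reach 0 from g0, via the fundamental
    matrix of the chain restricted to the transient states 1..N."""
    W = transition_matrix(model)
    Q = W[1:, 1:]
    t = np.linalg.solve(np.eye(model.N) - Q, np.ones(model.N))
    if g0 == 0:
        return 0.0
    return float(t[g0 - 1])


def mc_absorption_time(
    model: TransitionModel,
    g0: int,
    n_chains: int,
    seed: int,
    max_steps: int = 100_000,
) -> np.ndarray:
    """Monte-Carlo absorption times (steps to reach 0) from g0."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_chains, dtype=np.int64)
    for c in range(n_chains):
        g, k = g0, 0
        while g > 0:
            g = int(rng.binomial(model.N - g, model.p_of_g[g]))
            k += 1
            if k >= max_steps:
                raise RuntimeError("chain did not absorb within max_steps")
        out[c] = k
    return out


# --------------------------------------------------------------------------
# fixture calibration
# --------------------------------------------------------------------------


@dataclass
class CalibrationReport:
    """Outcome of the fixture search: accepted parameters and diagnostics."""

    params: ModelParams
    mod: DendriticModulation
    rate_nu: float
    fixed_points: FixedPointSet
    fixed_points_linear: FixedPointSet
    branching_ratio: float
    n_evaluated: int
    scanned: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "modulation": self.mod.to_dict(),
            "rate_nu": self.rate_nu,
            "fixed_points": self.fixed_points.to_dict(),
            "fixed_points_linear": self.fixed_points_linear.to_dict(),
            "branching_ratio": self.branching_ratio,
            "n_evaluated": self.n_evaluated,
            "scanned": self.scanned,
        }


def _theory_pipeline(
    params: ModelParams, mod: DendriticModulation, g_exact: int = 300
) -> tuple[float, StationaryDensity, TransitionModel]:
    nu = self_consistent_rate(params, mod)
    dens = stationary_density_diffusion(params, nu, mod)
    model = build_transition_model(params, mod, dens, g_exact=g_exact)
    return nu, dens, model


def calibrate_fixtures(
    search_space: dict,
    seed: int = 0,
    base: ModelParams | None = None,
    psi_plus_min_frac: float = 0.02,
    branching_max: float = 0.8,
    spontaneous_level: float = 5.0,
) -> CalibrationReport:
    """Search coupling and nonlinearity parameters for the reference regime.

    ``search_space`` maps any of ``I_ext, eps_exc, eps_inh, theta_b, theta_s,
    s_sat`` to a list of candidate values; the grid product is scanned in
    order.  A candidate is accepted iff, by the diffusion theory,

    * the background branching ratio E(1) stays below ``branching_max``
      (stable asynchronous background),
    * the nonlinear expectation curve has stable fixed points psi_minus <
      psi_zero < psi_plus with psi_plus >= psi_plus_min_frac * N, and
    * the same parameters with the identity modulation have no fixed point
      above the spontaneous coincidence level (no bistability without
      supra-additive coupling).

    Returns the report of the first accepted candidate; raises if the scanned
    region is empty of acceptable parameter sets.
    """
    if base is None:
        base = ModelParams(
            N=2000, p_conn=0.05, p_exc=0.8, eps_exc=0.01, eps_inh=-0.04
        )
    keys = sorted(search_space)
    n_eval = 0
    lin = DendriticModulation.identity()
    for combo in itertools.product(*(search_space[k] for k in keys)):
        cand = dict(zip(keys, combo))
        mod = DendriticModulation(
            theta_b=cand.pop("theta_b", 0.0) or 0.0,
            theta_s=cand.pop("theta_s", 0.0) or 0.0,
            s_sat=cand.pop("s_sat", 0.0) or 0.0,
        )
        params = base.replace(**cand)
        n_eval += 1
        try:
            nu, dens, model = _theory_pipeline(params, mod)
        except RuntimeError:
            continue
        E = model.E_curve
        branching = float(E[1])
        if branching > branching_max:
            continue
        fps = find_fixed_points(E)
        if not fps.bistable or fps.psi_plus < psi_plus_min_frac * params.N:
            continue
        _, _, model_lin = _theory_pipeline(params, lin)
        fps_lin = find_fixed_points(model_lin.E_curve)
        high_lin = [
            p
            for p in fps_lin.points
            if p.g > spontaneous_level and p.stability == "stable"
        ]
        if high_lin:
            continue
        return CalibrationReport(
            params=params,
            mod=mod,
            rate_nu=nu,
            fixed_points=fps,
            fixed_points_linear=fps_lin,
            branching_ratio=branching,
            n_evaluated=n_eval,
            scanned={k: list(search_space[k]) for k in keys},
        )
    raise RuntimeError(
        f"calibration failed: no acceptable parameter set among {n_eval} "
        f"candidates in ranges {{ {', '.join(f'{k}: {list(search_space[k])}' for k in keys)} }}"
    )
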