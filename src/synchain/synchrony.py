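"""Chain extraction, background pulse statistics, and stability classification.

A chain initiated at time t0 consists of the synchronous groups that spike at
exactly t0 + k*tau, k = 0, 1, 2, ... (within the simulator's simultaneity
tolerance): because the transmission delay is homogeneous, chain members send
precisely on this grid while background spikes fall at least slightly off it.
Spontaneously coincident background spikes form the noise floor — a run shows
*persistent propagation* when the background stays asynchronous (no pulse
above a fraction f_max of the network) and the first K_min chain groups all
exceed the largest background pulse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    CouplingMatrix,
    DendriticModulation,
    ModelParams,
    build_network,
    strengths_from_totals,
)
from .simulate import (
    TAG_CHAIN,
    TAG_STIMULUS,
    SimulationUnstable,
    SpikeRaster,
    StimulusProtocol,
    advance,
    equilibrate,
)

__all__ = [
    "Chain",
    "PulseSizeDistribution",
    "LABELS",
    "extract_chain",
    "background_pulses",
    "classify_run",
    "run_protocol",
    "ProtocolResult",
    "parameter_scan",
]

# stability labels, ordered worst -> best for majority tie-breaking
LABELS = (
    "unstable_bg_pre",
    "unstable_bg_post",
    "unstable_propagation",
    "stable_propagation",
)


@dataclass
class Chain:
    """Synchronous-group size sequence g_0 .. g_K of one initiated chain."""

    t0: float
    tau: float
    sizes: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)

    def __len__(self) -> int:
        return self.sizes.size

    @property
    def died(self) -> bool:
        return bool(np.any(self.sizes == 0))

    def to_frame(self) -> pd.DataFrame:
        k = np.arange(self.sizes.size)
        return pd.DataFrame(
            {"step": k, "time": self.t0 + k * self.tau, "size": self.sizes}
        )


@dataclass
class PulseSizeDistribution:
    """Histogram of synchronous-pulse sizes in background activity."""

    histogram: dict[int, int]
    window: tuple[float, float]

    @property
    def max_size(self) -> int:
        return max(self.histogram) if self.histogram else 0

    @property
    def n_pulses(self) -> int:
        return sum(self.histogram.values())

    def to_frame(self) -> pd.DataFrame:
        sizes = sorted(self.histogram)
        return pd.DataFrame(
            {"size": sizes, "count": [self.histogram[s] for s in sizes]}
        )


def extract_chain(
    raster: SpikeRaster,
    t0: float,
    tau: float,
    horizon: int,
    tol: float | None = None,
) -> Chain:
    """Extract the group sizes g_k at times t0 + k*tau, k = 0 .. horizon.

    Spikes matched to the grid (k >= 1) are tagged as chain members in the
    raster (in place); stimulus spikes at t0 keep their tag.  The sequence is
    truncated one step after the first empty group (the chain is dead from
    there on).
    """
    if raster.times.size and t0 < raster.times[0] - (tol or 1e-9 * tau):
        raise ValueError("t0 precedes the raster start")
    if tol is None:
        tol = 1e-9 * tau
    sizes = np.zeros(horizon + 1, dtype=np.int64)
    for k in range(horizon + 1):
        t_k = t0 + k * tau
        m = np.abs(raster.times - t_k) <= tol
        sizes[k] = int(np.count_nonzero(m))
        if k >= 1 and sizes[k] > 0:
            keep_stim = raster.tags[m] == TAG_STIMULUS
            raster.tags[m] = np.where(keep_stim, TAG_STIMULUS, TAG_CHAIN)
        if k >= 1 and sizes[k] == 0:
            sizes = sizes[: k + 1]
            break
    return Chain(t0=t0, tau=tau, sizes=sizes)


def background_pulses(
    raster: SpikeRaster,
    chain: Chain | None,
    window: tuple[float, float],
    tol: float | None = None,
) -> PulseSizeDistribution:
    """Group non-chain spikes by coincident times and histogram pulse sizes.

    The chain must have been extracted from the same raster first (its spikes
    carry the chain/stimulus tags and are excluded here).
    """
    if tol is None:
        tol = 1e-9 * (chain.tau if chain is not None else 1.0)
    t_start, t_end = window
    m = (
        (raster.times >= t_start)
        & (raster.times < t_end)
        & (raster.tags != TAG_CHAIN)
        & (raster.tags != TAG_STIMULUS)
    )
    times = np.sort(raster.times[m])
    hist: dict[int, int] = {}
    if times.size:
        # split runs of coincident spikes wherever the gap exceeds tol
        breaks = np.flatnonzero(np.diff(times) > tol)
        sizes = np.diff(np.concatenate([[0], breaks + 1, [times.size]]))
        for s in sizes[sizes > 0]:
            hist[int(s)] = hist.get(int(s), 0) + 1
    return PulseSizeDistribution(hist, window)


def classify_run(
    chain: Chain,
    bg_pre: PulseSizeDistribution,
    bg_post: PulseSizeDistribution,
    f_max: float,
    K_min: int,
    N: int,
) -> str:
    """Four-class stability label of one stimulated run.

    * ``unstable_bg_pre``  — a pre-stimulus background pulse exceeds f_max*N;
    * ``unstable_bg_post`` — a post-stimulus background pulse exceeds f_max*N;
    * ``stable_propagation`` — the first K_min chain groups all exceed the
      largest observed background pulse;
    * ``unstable_propagation`` — otherwise (chain indistinguishable from or
      below the background coincidence level).
    """
    if K_min >= len(chain.sizes) and not chain.died:
        raise ValueError(
            f"K_min={K_min} exceeds the observed chain horizon {len(chain.sizes) - 1}"
        )
    if bg_pre.max_size > f_max * N:
        return "unstable_bg_pre"
    if bg_post.max_size > f_max * N:
        return "unstable_bg_post"
    bg_max = max(bg_pre.max_size, bg_post.max_size)
    g = chain.sizes[1 : K_min + 1]
    if g.size >= K_min and np.all(g > bg_max):
        return "stable_propagation"
    return "unstable_propagation"


@dataclass
class ProtocolResult:
    """Everything measured in one equilibrate -> stimulate -> classify run."""

    label: str
    chain: Chain | None
    bg_pre: PulseSizeDistribution | None
    bg_post: PulseSizeDistribution | None
    raster: SpikeRaster | None = None
    rate: float = float("nan")


def run_protocol(
    params: ModelParams,
    matrix: CouplingMatrix,
    mod: DendriticModulation,
    g0: int,
    seed: int,
    t_eq: float = 50.0,
    pre_window: float = 50.0,
    post_window: float = 20.0,
    K_min: int = 20,
    horizon: int | None = None,
    f_max: float = 0.1,
    stim_prefix: bool = False,
    keep_raster: bool = False,
) -> ProtocolResult:
    """Full single-run protocol: equilibrate, observe background, stimulate
    g0 neurons, follow the chain for ``horizon`` steps, observe background
    again, classify.

    Simulation aborts (spike-rate explosion) are mapped onto the unstable
    background labels according to whether they occur before or after the
    stimulus.
    """
    if horizon is None:
        horizon = max(K_min, 50)
    ss = np.random.SeedSequence(seed)
    s_eq, s_stim = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    try:
        state = equilibrate(params, matrix, mod, t_eq, seed=s_eq)
        pre_raster, state = advance(state, params, matrix, mod, pre_window)
    except SimulationUnstable:
        return ProtocolResult("unstable_bg_pre", None, None, None)

    t0 = state.t_now
    stim = StimulusProtocol.single(t0, g0, params.N, seed=s_stim, prefix=stim_prefix)
    chain_span = (horizon + 1) * params.tau
    try:
        post_raster, state = advance(
            state, params, matrix, mod, chain_span + post_window, stim=stim
        )
    except SimulationUnstable:
        return ProtocolResult("unstable_bg_post", None, None, None)

    raster = SpikeRaster.concat([pre_raster, post_raster])
    # tag the chain grid over the whole observed window: a persistent chain
    # keeps firing during the post-stimulus background check and must not be
    # mistaken for background coincidences there
    horizon_full = int(np.ceil((chain_span + post_window) / params.tau)) + 1
    chain = extract_chain(raster, t0, params.tau, horizon_full)
    bg_pre = background_pulses(raster, chain, (t0 - pre_window, t0))
    bg_post = background_pulses(raster, chain, (t0, t0 + chain_span + post_window))
    label = classify_run(chain, bg_pre, bg_post, f_max, K_min, params.N)
    rate = len(raster) / (params.N * (pre_window + chain_span + post_window))
    return ProtocolResult(
        label,
        chain,
        bg_pre,
        bg_post,
        raster if keep_raster else None,
        rate,
    )


def parameter_scan(
    base: ModelParams,
    mod: DendriticModulation,
    E_grid,
    I_grid,
    g0: int,
    n_nets: int,
    seed: int,
    completed: pd.DataFrame | None = None,
    on_cell=None,
    **protocol_kwargs,
) -> pd.DataFrame:
    """Scan the mean total input strengths (E_tot, I_tot) for propagation.

    For every grid cell the coupling strengths are set via
    :func:`strengths_from_totals`; ``n_nets`` independent networks and initial
    conditions are run through :func:`run_protocol` and the cell label is the
    majority vote (ties resolved towards the worst label in the order
    unstable_bg_pre < unstable_bg_post < unstable_propagation <
    stable_propagation).  Returns a long-format table with per-label counts.

    ``completed`` (a previous partial result) lets an interrupted scan resume:
    finished cells are copied over without re-running.  ``on_cell`` is called
    with each finished row (used for incremental persistence and logging).
    """
    E_grid = list(E_grid)
    I_grid = list(I_grid)
    if not E_grid or not I_grid:
        raise ValueError("scan grids must be non-empty")
    done: dict[tuple[float, float], dict] = {}
    if completed is not None and len(completed):
        for _, row in completed.iterrows():
            done[(float(row["E_tot"]), float(row["I_tot"]))] = row.to_dict()

    root = np.random.SeedSequence(seed)
    rows = []
    for iE, E_tot in enumerate(E_grid):
        for iI, I_tot in enumerate(I_grid):
            key = (float(E_tot), float(I_tot))
            if key in done:
                rows.append(done[key])
                continue
            cell_ss = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(iE, iI)
            )
            params = strengths_from_totals(base, E_tot, I_tot)
            counts = dict.fromkeys(LABELS, 0)
            for j, child in enumerate(cell_ss.spawn(n_nets)):
                net_seed, run_seed = (
                    int(s.generate_state(1)[0] % 2**31) for s in child.spawn(2)
                )
                matrix = build_network(params, net_seed)
                res = run_protocol(
                    params, matrix, mod, g0, run_seed, **protocol_kwargs
                )
                counts[res.label] += 1
            best = max(counts.values())
            label = next(l for l in LABELS if counts[l] == best)
            row = {
                "E_tot": float(E_tot),
                "I_tot": float(I_tot),
                "n_stable": counts["stable_propagation"],
                "n_unstable_prop": counts["unstable_propagation"],
                "n_bg_pre": counts["unstable_bg_pre"],
                "n_bg_post": counts["unstable_bg_post"],
                "label": label,
            }
            rows.append(row)
            if on_cell is not None:
                on_cell(row)
    return pd.DataFrame(rows)
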