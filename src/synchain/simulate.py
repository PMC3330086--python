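"""Exact event-driven simulation of the delayed delta-coupled LIF network.

The algorithm keeps, for every neuron, its *pseudo-spike time* — the absolute
time at which it would next cross threshold if it received no further input —
plus a FIFO queue of spikes in transit (emission time + tau).  Because the
delay tau is homogeneous, arrival times are generated in non-decreasing order
and the queue never needs sorting.  In each step the smallest pseudo-spike
time is compared with the next arrival (and the next stimulus pulse) and the
earlier event is processed:

* sending event — all neurons whose pseudo-spike times coincide (within the
  grouping tolerance) emit together; their spikes are enqueued to arrive tau
  later and their phases reset;
* stimulus event — the listed neurons are forced to spike immediately
  (external supra-threshold input), joining the outgoing wave;
* receiving event — all spikes with the same arrival time form one wave; per
  postsynaptic neuron the excitatory strengths are summed, passed through the
  dendritic modulation sigma, the (linear) inhibitory sum is added, and the
  phase is updated synchronously from its pre-delivery value.  Neurons pushed
  to or above threshold spike immediately at the arrival time and their spikes
  join the same outgoing wave.

At coincident instants the processing order is: free threshold crossings,
then stimuli, then deliveries — all stamped with the same event time.
Simultaneity is decided with tolerance ``1e-9 * tau`` to absorb float drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .model import CouplingMatrix, DendriticModulation, ModelParams
from .phase import PhaseFunctions

__all__ = [
    "SimState",
    "SpikeRaster",
    "StimulusProtocol",
    "SimulationUnstable",
    "TAG_BACKGROUND",
    "TAG_CHAIN",
    "TAG_STIMULUS",
    "init_state",
    "equilibrate",
    "advance",
    "simulate",
    "deliver_wave",
    "sample_potentials",
]

TAG_BACKGROUND = 0
TAG_CHAIN = 1
TAG_STIMULUS = 2
TAG_NAMES = {TAG_BACKGROUND: "background", TAG_CHAIN: "chain", TAG_STIMULUS: "stimulus"}


class SimulationUnstable(RuntimeError):
    """Raised when the spike-rate explosion guard trips (unstable background)."""

    def __init__(self, message: str, raster: "SpikeRaster | None" = None):
        super().__init__(message)
        self.raster = raster


@dataclass
class StimulusProtocol:
    """External supra-threshold pulses: list of (time, neuron id array)."""

    pulses: list[tuple[float, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        norm = []
        for t, ids in sorted(self.pulses, key=lambda p: p[0]):
            ids = np.asarray(ids, dtype=np.int64)
            if t < 0:
                raise ValueError("stimulus times must be >= 0")
            if ids.size == 0:
                raise ValueError("stimulus target sets must be non-empty")
            norm.append((float(t), ids))
        self.pulses = norm

    @classmethod
    def single(
        cls,
        t0: float,
        g0: int,
        N: int,
        seed: int | None = None,
        prefix: bool = False,
    ) -> "StimulusProtocol":
        """One pulse of g0 neurons at time t0.

        Default targets are a uniformly random g0-subset; ``prefix=True``
        selects neurons 0..g0-1 instead (index-prefix mode).
        """
        if not 1 <= g0 <= N:
            raise ValueError("g0 must lie in [1, N]")
        if prefix:
            ids = np.arange(g0, dtype=np.int64)
        else:
            rng = np.random.default_rng(seed)
            ids = rng.choice(N, size=g0, replace=False).astype(np.int64)
        return cls([(t0, ids)])


@dataclass
class SpikeRaster:
    """Time-ordered spikes: (time, neuron id, tag)."""

    times: np.ndarray
    ids: np.ndarray
    tags: np.ndarray

    def __len__(self) -> int:
        return self.times.size

    def window(self, t_start: float, t_end: float) -> "SpikeRaster":
        m = (self.times >= t_start) & (self.times < t_end)
        return SpikeRaster(self.times[m], self.ids[m], self.tags[m])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "neuron": self.ids,
                "tag": [TAG_NAMES[t] for t in self.tags],
            }
        )

    def to_csv(self, path, config_hash: str | None = None) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            if config_hash is not None:
                fh.write(f"# config_hash={config_hash}\n")
            # %.17g keeps spike times exact through the round trip
            self.to_frame().to_csv(fh, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "SpikeRaster":
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        inv = {v: k for k, v in TAG_NAMES.items()}
        return cls(
            df["time"].to_numpy(float),
            df["neuron"].to_numpy(np.int64),
            np.array([inv[t] for t in df["tag"]], dtype=np.int8),
        )

    @staticmethod
    def concat(rasters: list["SpikeRaster"]) -> "SpikeRaster":
        return SpikeRaster(
            np.concatenate([r.times for r in rasters]),
            np.concatenate([r.ids for r in rasters]),
            np.concatenate([r.tags for r in rasters]),
        )


@dataclass
class SimState:
    """Simulator state: per-neuron pseudo-spike times plus spikes in transit.

    ``next_spike[i]`` is the absolute time of neuron i's next threshold
    crossing absent further input; the phase at clock time t is
    ``phi_theta - (next_spike[i] - t)``.
    """

    t_now: float
    next_spike: np.ndarray
    q_time: np.ndarray
    q_sender: np.ndarray
    rng_seed: int
    n_clamped: int = 0

    @property
    def N(self) -> int:
        return self.next_spike.size

    def phases(self, pf: PhaseFunctions) -> np.ndarray:
        return pf.phi_theta - (self.next_spike - self.t_now)

    def potentials(self, pf: PhaseFunctions) -> np.ndarray:
        return pf.U(self.phases(pf))

    @property
    def in_transit(self) -> list[tuple[float, int]]:
        return list(zip(self.q_time.tolist(), self.q_sender.tolist()))

    def copy(self) -> "SimState":
        return SimState(
            self.t_now,
            self.next_spike.copy(),
            self.q_time.copy(),
            self.q_sender.copy(),
            self.rng_seed,
            self.n_clamped,
        )


@njit(cache=False)
def _run_kernel(
    next_spike,
    t_start,
    t_end,
    indptr,
    indices,
    data,
    q_time,
    q_sender,
    q_head,
    q_len,
    stim_time,
    stim_offsets,
    stim_targets,
    gamma,
    V_inf,
    V_theta,
    V_reset,
    phi_theta,
    tau,
    lin_mod,
    theta_b,
    theta_s,
    s_sat,
    max_spikes,
    rec_time,
    rec_id,
    rec_tag,
):
    N = next_spike.size
    tol = 1e-9 * tau
    n_stim = stim_time.size
    stim_idx = 0
    # skip stimuli already in the past (should not happen; defensive)
    while stim_idx < n_stim and stim_time[stim_idx] < t_start - tol:
        stim_idx += 1

    exc = np.zeros(N)
    inh = np.zeros(N)
    stamp = np.full(N, -1, dtype=np.int64)
    touched = np.empty(N, dtype=np.int64)
    senders = np.empty(N, dtype=np.int64)
    if lin_mod or theta_s == theta_b:
        ramp = 0.0
    else:
        ramp = (s_sat - theta_b) / (theta_s - theta_b)

    n_rec = 0
    n_clamped = 0
    event_id = 0
    status = 0

    while True:
        t_spike = np.inf
        for i in range(N):
            if next_spike[i] < t_spike:
                t_spike = next_spike[i]
        t_arr = q_time[q_head] if q_head < q_len else np.inf
        t_st = stim_time[stim_idx] if stim_idx < n_stim else np.inf
        t_next = min(t_spike, t_arr, t_st)
        if t_next > t_end:
            break

        if t_spike <= t_next + tol:
            # sending event: all coincident free threshold crossings
            for i in range(N):
                if next_spike[i] <= t_next + tol:
                    if n_rec >= max_spikes:
                        status = 1
                        break
                    rec_time[n_rec] = t_next
                    rec_id[n_rec] = i
                    rec_tag[n_rec] = 0
                    n_rec += 1
                    q_time[q_len] = t_next + tau
                    q_sender[q_len] = i
                    q_len += 1
                    next_spike[i] = t_next + phi_theta
            if status:
                break
        elif t_st <= t_arr + tol:
            # stimulus pulse: forced spikes (skip neurons that just spiked now)
            for k in range(stim_offsets[stim_idx], stim_offsets[stim_idx + 1]):
                i = stim_targets[k]
                if abs(next_spike[i] - (t_next + phi_theta)) < tol:
                    continue
                if n_rec >= max_spikes:
                    status = 1
                    break
                rec_time[n_rec] = t_next
                rec_id[n_rec] = i
                rec_tag[n_rec] = 2
                n_rec += 1
                q_time[q_len] = t_next + tau
                q_sender[q_len] = i
                q_len += 1
                next_spike[i] = t_next + phi_theta
            stim_idx += 1
            if status:
                break
        else:
            # receiving event: one synchronous wave
            n_senders = 0
            while q_head < q_len and q_time[q_head] <= t_next + tol:
                senders[n_senders] = q_sender[q_head]
                n_senders += 1
                q_head += 1
            n_touched = 0
            for si in range(n_senders):
                s = senders[si]
                for k in range(indptr[s], indptr[s + 1]):
                    i = indices[k]
                    w = data[k]
                    if stamp[i] != event_id:
                        stamp[i] = event_id
                        exc[i] = 0.0
                        inh[i] = 0.0
                        touched[n_touched] = i
                        n_touched += 1
                    if w > 0.0:
                        exc[i] += w
                    else:
                        inh[i] += w
            # synchronous update from pre-delivery phases
            for idx in range(n_touched):
                i = touched[idx]
                phi = phi_theta - (next_spike[i] - t_next)
                e = np.exp(-gamma * phi)
                V = V_inf * (1.0 - e) + V_reset * e
                x = exc[i]
                if lin_mod:
                    sx = x
                elif x <= theta_b:
                    sx = x
                elif x >= theta_s:
                    sx = s_sat
                else:
                    sx = theta_b + ramp * (x - theta_b)
                V_new = V + sx + inh[i]
                if V_new >= V_theta:
                    if n_rec >= max_spikes:
                        status = 1
                        break
                    rec_time[n_rec] = t_next
                    rec_id[n_rec] = i
                    rec_tag[n_rec] = 0
                    n_rec += 1
                    q_time[q_len] = t_next + tau
                    q_sender[q_len] = i
                    q_len += 1
                    next_spike[i] = t_next + phi_theta
                else:
                    if V_new <= -V_inf:
                        V_new = -V_inf
                        n_clamped += 1
                    phi_new = (
                        -np.log((V_inf - V_new) / (V_inf - V_reset)) / gamma
                    )
                    next_spike[i] = t_next + (phi_theta - phi_new)
            event_id += 1
            if status:
                break

    return status, n_rec, q_head, q_len, n_clamped


def init_state(
    params: ModelParams, seed: int, n_transit_init: int | None = None
) -> SimState:
    """Random initial condition: phases uniform on [0, phi_theta) and
    ``n_transit_init`` random spikes already in transit (default N * p_conn)."""
    pf = PhaseFunctions.from_params(params)
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, pf.phi_theta, size=params.N)
    next_spike = pf.phi_theta - phases
    if n_transit_init is None:
        n_transit_init = int(round(params.N * params.p_conn))
    q_time = np.sort(rng.uniform(0.0, params.tau, size=n_transit_init))
    q_sender = rng.integers(0, params.N, size=n_transit_init).astype(np.int64)
    return SimState(0.0, next_spike, q_time, q_sender, int(seed))


def _flatten_stim(stim: StimulusProtocol | None):
    if stim is None or not stim.pulses:
        return (
            np.empty(0, dtype=float),
            np.zeros(1, dtype=np.int64),
            np.empty(0, dtype=np.int64),
        )
    times = np.array([t for t, _ in stim.pulses], dtype=float)
    offsets = np.zeros(len(stim.pulses) + 1, dtype=np.int64)
    offsets[1:] = np.cumsum([ids.size for _, ids in stim.pulses])
    targets = np.concatenate([ids for _, ids in stim.pulses]).astype(np.int64)
    return times, offsets, targets


def advance(
    state: SimState,
    params: ModelParams,
    matrix: CouplingMatrix,
    mod: DendriticModulation,
    duration: float,
    stim: StimulusProtocol | None = None,
    guard_rate: float | None = None,
) -> tuple[SpikeRaster, SimState]:
    """Run the event loop for ``duration`` from ``state`` (not mutated).

    Returns the raster of the interval and the final state.  Raises
    :class:`SimulationUnstable` when the explosion guard (``guard_rate``
    spikes per neuron per unit time, default 25 / T_free) trips.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    pf = PhaseFunctions.from_params(params)
    new = state.copy()
    if duration == 0 and stim is None:
        return SpikeRaster(
            np.empty(0), np.empty(0, np.int64), np.empty(0, np.int8)
        ), new

    t_end = state.t_now + duration
    if guard_rate is None:
        guard_rate = 25.0 / pf.T_free
    stim_time, stim_offsets, stim_targets = _flatten_stim(stim)
    max_spikes = int(guard_rate * params.N * max(duration, params.tau)) + (
        10 * params.N + stim_targets.size + 16
    )
    # queue capacity: every recorded spike enqueues exactly one arrival
    cap = new.q_time.size + max_spikes
    q_time = np.empty(cap, dtype=float)
    q_sender = np.empty(cap, dtype=np.int64)
    q_time[: new.q_time.size] = new.q_time
    q_sender[: new.q_sender.size] = new.q_sender

    rec_time = np.empty(max_spikes, dtype=float)
    rec_id = np.empty(max_spikes, dtype=np.int64)
    rec_tag = np.empty(max_spikes, dtype=np.int8)

    csr = matrix.csr
    status, n_rec, q_head, q_len, n_clamped = _run_kernel(
        new.next_spike,
        state.t_now,
        t_end,
        csr.indptr.astype(np.int64),
        csr.indices.astype(np.int64),
        csr.data.astype(float),
        q_time,
        q_sender,
        0,
        new.q_time.size,
        stim_time,
        stim_offsets,
        stim_targets,
        params.gamma,
        pf.V_inf,
        params.V_theta,
        params.V_reset,
        pf.phi_theta,
        params.tau,
        mod.linear,
        mod.theta_b,
        mod.theta_s,
        mod.s_sat,
        max_spikes,
        rec_time,
        rec_id,
        rec_tag,
    )
    raster = SpikeRaster(
        rec_time[:n_rec].copy(), rec_id[:n_rec].copy(), rec_tag[:n_rec].copy()
    )
    if status != 0:
        raise SimulationUnstable(
            f"spike-rate explosion guard tripped: {n_rec} spikes within "
            f"{duration} time units (guard {guard_rate:.3g}/neuron/time); "
            "background activity is unstable",
            raster=raster,
        )
    new.t_now = t_end
    new.q_time = q_time[q_head:q_len].copy()
    new.q_sender = q_sender[q_head:q_len].copy()
    new.n_clamped += n_clamped
    return raster, new


def equilibrate(
    params: ModelParams,
    matrix: CouplingMatrix,
    mod: DendriticModulation,
    t_eq: float,
    seed: int,
    n_transit_init: int | None = None,
    guard_rate: float | None = None,
) -> SimState:
    """Sample a random initial condition and relax it for ``t_eq``.

    ``t_eq = 0`` returns the sampled initial condition unchanged.
    """
    if t_eq < 0:
        raise ValueError("t_eq must be >= 0")
    state = init_state(params, seed, n_transit_init=n_transit_init)
    if t_eq == 0:
        return state
    _, state = advance(state, params, matrix, mod, t_eq, guard_rate=guard_rate)
    return state


def simulate(
    params: ModelParams,
    matrix: CouplingMatrix,
    mod: DendriticModulation,
    duration: float,
    stim: StimulusProtocol | None,
    seed: int,
    from_state: SimState | None = None,
    guard_rate: float | None = None,
) -> SpikeRaster:
    """Simulate for ``duration`` and return the raster.

    Starts from a fresh random initial condition (given ``seed``) unless
    ``from_state`` is supplied.  Identical seeds and configurations yield
    bit-identical rasters.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    state = from_state if from_state is not None else init_state(params, seed)
    raster, _ = advance(
        state, params, matrix, mod, duration, stim=stim, guard_rate=guard_rate
    )
    return raster


def deliver_wave(
    state: SimState,
    arrivals,
    matrix: CouplingMatrix,
    mod: DendriticModulation,
    pf: PhaseFunctions,
    tau: float | None = None,
) -> np.ndarray:
    """Deliver one synchronous wave from ``arrivals`` (sender ids) at the
    state's current clock time and return the array of neurons that fire.

    Per postsynaptic neuron the excitatory strengths are summed and modulated
    by sigma, the inhibitory sum is added linearly, and the update uses the
    pre-delivery phase of every neuron (synchronous update).  Firing neurons
    reset; when ``tau`` is given their spikes are enqueued to arrive ``tau``
    later.  The state is mutated in place.  Reference implementation of the
    kernel's receiving event, also used directly for single-wave experiments.
    """
    senders = np.asarray(list(arrivals), dtype=np.int64)
    exc, inh = matrix.wave_input(senders)
    t = state.t_now
    phi = pf.phi_theta - (state.next_spike - t)
    V = pf.U(phi)
    lam = mod(np.maximum(exc, 0.0)) + inh
    touched = (exc != 0) | (inh != 0)
    V_new = V + np.where(touched, lam, 0.0)
    fired = touched & (V_new >= pf.V_theta)
    sub = touched & ~fired
    V_sub = np.clip(V_new[sub], -pf.V_inf, None)
    state.next_spike[sub] = t + (pf.phi_theta - pf.U_inv(V_sub))
    state.next_spike[fired] = t + pf.phi_theta
    fired_ids = np.flatnonzero(fired).astype(np.int64)
    if tau is not None and fired_ids.size:
        state.q_time = np.concatenate(
            [state.q_time, np.full(fired_ids.size, t + tau)]
        )
        state.q_sender = np.concatenate([state.q_sender, fired_ids])
    return fired_ids


def sample_potentials(
    state: SimState,
    params: ModelParams,
    matrix: CouplingMatrix,
    mod: DendriticModulation,
    n_snapshots: int,
    interval: float,
    guard_rate: float | None = None,
) -> tuple[np.ndarray, SimState]:
    """Collect membrane-potential snapshots every ``interval`` time units.

    Returns an array of shape (n_snapshots, N) and the advanced state.
    """
    pf = PhaseFunctions.from_params(params)
    out = np.empty((n_snapshots, params.N))
    for k in range(n_snapshots):
        _, state = advance(
            state, params, matrix, mod, interval, guard_rate=guard_rate
        )
        out[k] = state.potentials(pf)
    return out, state
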