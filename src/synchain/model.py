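"""Network and neuron parameters, the dendritic modulation function, and
random-network construction.

The neuron is a leaky integrate-and-fire (LIF) unit driven by a constant
supra-threshold current ``I_ext`` and coupled through delayed delta synapses.
Excitatory inputs arriving simultaneously at a neuron are summed linearly and
then passed through a piecewise-linear sigmoid ("dendritic modulation
function") that models the supra-additive amplification produced by fast
dendritic sodium spikes: identity below an onset threshold ``theta_b``,
saturation at ``s_sat`` above ``theta_s``, affine in between.  Inhibitory
inputs always sum linearly and bypass the modulation.

Connectivity is a directed Erdős–Rényi graph: every ordered pair of distinct
neurons carries a synapse independently with probability ``p_conn``; a present
synapse is excitatory (strength ``eps_exc``) with probability ``p_exc`` and
inhibitory (``eps_inh``) otherwise, independently per connection (no Dale's
law).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ModelParams",
    "DendriticModulation",
    "CouplingMatrix",
    "sigma_modulate",
    "build_network",
    "mean_total_input_strengths",
    "strengths_from_totals",
]


@dataclass(frozen=True)
class ModelParams:
    """All scalar parameters of the network model.

    Units: potentials are measured with threshold ``V_theta = 1`` and reset
    ``V_reset = 0`` by convention; time is measured in membrane time
    constants when ``gamma = 1``.
    """

    N: int
    p_conn: float
    p_exc: float
    eps_exc: float
    eps_inh: float
    gamma: float = 1.0
    I_ext: float = 1.25
    V_theta: float = 1.0
    V_reset: float = 0.0
    tau: float = 0.1

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        if not 0.0 <= self.p_conn <= 1.0:
            raise ValueError(f"p_conn must lie in [0, 1], got {self.p_conn}")
        if not 0.0 <= self.p_exc <= 1.0:
            raise ValueError(f"p_exc must lie in [0, 1], got {self.p_exc}")
        if self.eps_exc < 0:
            raise ValueError("eps_exc must be >= 0 (excitatory strength)")
        if self.eps_inh > 0:
            raise ValueError("eps_inh must be <= 0 (inhibitory strength)")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.V_reset >= self.V_theta:
            raise ValueError("V_reset must be < V_theta")
        if self.I_ext <= self.gamma * self.V_theta:
            raise ValueError(
                "supra-threshold drive required: I_ext > gamma * V_theta "
                f"(got I_ext={self.I_ext}, gamma*V_theta={self.gamma * self.V_theta})"
            )

    @property
    def p_inh(self) -> float:
        """Probability that a realized connection is inhibitory (1 - p_exc)."""
        return 1.0 - self.p_exc

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParams":
        d = dict(d)
        d.pop("p_inh", None)  # derived, tolerated on input
        return cls(**d)


@dataclass(frozen=True)
class DendriticModulation:
    """Piecewise-linear sigmoid sigma(x) applied to summed synchronous EPSPs.

    sigma(x) = x                for 0 <= x <= theta_b
             = s_sat            for x >= theta_s
             = affine ramp      in between (continuous at both knots)

    ``linear=True`` selects the identity limit (purely additive coupling).
    """

    theta_b: float = 0.0
    theta_s: float = 0.0
    s_sat: float = 0.0
    linear: bool = False

    def __post_init__(self) -> None:
        if self.linear:
            return
        if self.theta_b <= 0:
            raise ValueError("theta_b must be > 0")
        if self.theta_s < self.theta_b:
            raise ValueError("theta_s must be >= theta_b")
        if self.s_sat < self.theta_b:
            raise ValueError("s_sat must be >= theta_b (sigma non-decreasing)")

    @classmethod
    def identity(cls) -> "DendriticModulation":
        return cls(linear=True)

    def __call__(self, x):
        return sigma_modulate(x, self)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "DendriticModulation":
        return cls(**dict(d))


def sigma_modulate(x, mod: DendriticModulation):
    """Apply the dendritic modulation function to summed excitatory input x.

    Accepts scalars or arrays; x must be non-negative (inhibition is never
    passed through sigma).
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("sigma is defined for non-negative summed EPSPs only")
    if mod.linear:
        out = arr.copy()
    elif mod.theta_s == mod.theta_b:
        # degenerate ramp: step from identity to saturation at the knot
        out = np.where(arr < mod.theta_b, arr, mod.s_sat)
    else:
        slope = (mod.s_sat - mod.theta_b) / (mod.theta_s - mod.theta_b)
        out = np.where(
            arr <= mod.theta_b,
            arr,
            np.where(
                arr >= mod.theta_s,
                mod.s_sat,
                mod.theta_b + slope * (arr - mod.theta_b),
            ),
        )
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


class CouplingMatrix:
    """Directed synaptic coupling, wrapped around a CSR sparse matrix.

    ``matrix[j, i]`` is the strength of the synapse from presynaptic neuron j
    onto postsynaptic neuron i (rows index senders).  Present strengths are
    exactly ``eps_exc`` (> 0) or ``eps_inh`` (< 0); absent pairs carry no
    synapse.
    """

    def __init__(self, matrix: sp.spmatrix, N: int | None = None):
        csr = sp.csr_matrix(matrix)
        if N is not None and csr.shape != (N, N):
            raise ValueError(f"expected shape {(N, N)}, got {csr.shape}")
        if csr.shape[0] != csr.shape[1]:
            raise ValueError("coupling matrix must be square")
        csr.sort_indices()
        self.csr = csr

    @property
    def N(self) -> int:
        return self.csr.shape[0]

    @property
    def n_synapses(self) -> int:
        return self.csr.nnz

    def out_degree(self) -> np.ndarray:
        return np.diff(self.csr.indptr)

    def in_degree(self) -> np.ndarray:
        return np.asarray((self.csr != 0).sum(axis=0)).ravel()

    def wave_input(self, senders: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Summed excitatory and (signed) inhibitory input to every neuron
        from one synchronous wave sent by ``senders``."""
        sub = self.csr[np.asarray(senders, dtype=np.intp)]
        exc = np.asarray(sub.multiply(sub > 0).sum(axis=0)).ravel()
        inh = np.asarray(sub.multiply(sub < 0).sum(axis=0)).ravel()
        return exc, inh

    def to_frame(self) -> pd.DataFrame:
        coo = self.csr.tocoo()
        return pd.DataFrame(
            {"pre_id": coo.row, "post_id": coo.col, "strength": coo.data}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, N: int) -> "CouplingMatrix":
        df = pd.read_csv(path)
        mat = sp.coo_matrix(
            (df["strength"], (df["pre_id"], df["post_id"])), shape=(N, N)
        )
        return cls(mat)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CouplingMatrix):
            return NotImplemented
        return (self.csr != other.csr).nnz == 0


def build_network(
    params: ModelParams, seed: int, allow_self: bool = False
) -> CouplingMatrix:
    """Draw a directed Erdős–Rényi network with per-connection signed strengths.

    Each ordered pair (j, i), j != i, carries a synapse independently with
    probability ``p_conn``; a present synapse is excitatory with probability
    ``p_exc``, inhibitory otherwise.  Reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    N = params.N
    # Sample the number of edges, then edge identities without replacement;
    # equivalent to independent Bernoulli over ordered pairs.
    n_pairs = N * N if allow_self else N * (N - 1)
    n_edges = rng.binomial(n_pairs, params.p_conn)
    flat = rng.choice(n_pairs, size=n_edges, replace=False)
    if allow_self:
        pre, post = np.divmod(flat, N)
    else:
        pre, off = np.divmod(flat, N - 1)
        post = off + (off >= pre)  # skip the diagonal
    signs = rng.random(n_edges) < params.p_exc
    data = np.where(signs, params.eps_exc, params.eps_inh).astype(float)
    mat = sp.coo_matrix((data, (pre, post)), shape=(N, N))
    return CouplingMatrix(mat, N=N)


def mean_total_input_strengths(params: ModelParams) -> tuple[float, float]:
    """Mean total excitatory / inhibitory input strength per neuron.

    E_tot = N * p_conn * p_exc * eps_exc,  I_tot = N * p_conn * p_inh * eps_inh
    (signed).  These are the natural axes for coupling-strength scans.
    """
    base = params.N * params.p_conn
    return (
        base * params.p_exc * params.eps_exc,
        base * params.p_inh * params.eps_inh,
    )


def strengths_from_totals(
    params: ModelParams, E_tot: float, I_tot: float
) -> ModelParams:
    """Inverse of :func:`mean_total_input_strengths` at fixed topology statistics."""
    base = params.N * params.p_conn
    if base == 0 or params.p_exc == 0:
        raise ValueError("cannot invert: N * p_conn * p_exc is zero")
    eps_exc = E_tot / (base * params.p_exc)
    if params.p_inh == 0:
        if I_tot != 0:
            raise ValueError("I_tot must be 0 when p_inh = 0")
        eps_inh = 0.0
    else:
        eps_inh = I_tot / (base * params.p_inh)
    return params.replace(eps_exc=eps_exc, eps_inh=eps_inh)
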