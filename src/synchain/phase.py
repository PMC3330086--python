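"""Closed-form phase representation of the LIF neuron.

Between events the membrane potential of a neuron driven by a constant
supra-threshold current obeys dV/dt = -gamma*V + I_ext, which integrates to

    U(phi) = (I_ext/gamma) * (1 - exp(-gamma*phi)) + V_reset * exp(-gamma*phi)

where the phase ``phi`` is simply the time elapsed since the last reset (it
advances with unit slope between events).  ``U`` is strictly increasing and
concave, so potentials map one-to-one to phases; delta-synapse inputs of total
strength ``lam`` act through the response function

    H_lam(phi) = U^{-1}(U(phi) + lam),

with an immediate spike (and reset to phase 0) whenever U(phi) + lam reaches
or exceeds the threshold.  Potentials below V_reset are represented by
negative phases through the same closed form; there is no lower barrier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import ModelParams

__all__ = ["PhaseFunctions", "free_period", "apply_input"]


def free_period(params: ModelParams) -> float:
    """Inter-spike interval of an uncoupled neuron.

    T_free = (1/gamma) * ln[(I_ext - gamma*V_reset) / (I_ext - gamma*V_theta)].
    Equals the phase threshold phi_theta.
    """
    g, I = params.gamma, params.I_ext
    num = I - g * params.V_reset
    den = I - g * params.V_theta
    if den <= 0:
        raise ValueError(
            "free period undefined: drive must exceed gamma * V_theta"
        )
    return float(np.log(num / den) / g)


@dataclass(frozen=True)
class PhaseFunctions:
    """Potential <-> phase maps for a fixed parameter set."""

    gamma: float
    I_ext: float
    V_theta: float
    V_reset: float
    phi_theta: float

    @classmethod
    def from_params(cls, params: ModelParams) -> "PhaseFunctions":
        return cls(
            gamma=params.gamma,
            I_ext=params.I_ext,
            V_theta=params.V_theta,
            V_reset=params.V_reset,
            phi_theta=free_period(params),
        )

    @property
    def T_free(self) -> float:
        return self.phi_theta

    @property
    def V_inf(self) -> float:
        """Asymptotic potential I_ext/gamma (never reached; above threshold)."""
        return self.I_ext / self.gamma

    def U(self, phi):
        """Potential at phase phi (valid for any real phi <= phi_theta)."""
        e = np.exp(-self.gamma * np.asarray(phi, dtype=float))
        out = self.V_inf * (1.0 - e) + self.V_reset * e
        return float(out) if np.ndim(phi) == 0 else out

    def U_inv(self, V):
        """Phase at potential V; defined for all V < I_ext/gamma."""
        V = np.asarray(V, dtype=float)
        ratio = (self.V_inf - V) / (self.V_inf - self.V_reset)
        if np.any(ratio <= 0):
            raise ValueError("U_inv undefined for V >= I_ext/gamma")
        out = -np.log(ratio) / self.gamma
        return float(out) if out.ndim == 0 else out


def apply_input(
    phi: float, lam: float, pf: PhaseFunctions
) -> tuple[float, bool]:
    """Update a neuron's phase for a delta input of total strength ``lam``.

    Returns ``(phi_new, fired)``.  Firing uses the >= convention (a potential
    exactly at threshold spikes); on reset the overshoot is discarded and the
    phase is set to 0 exactly.  Negative ``lam`` may push the phase below 0
    (potential below reset).
    """
    if phi > pf.phi_theta + 1e-12:
        raise ValueError("phase beyond threshold passed to apply_input")
    V_new = pf.U(phi) + lam
    if V_new >= pf.V_theta:
        return 0.0, True
    floor = -pf.V_inf
    if V_new <= floor:
        warnings.warn(
            f"potential clamped at {floor:.6g} after input lam={lam:.6g}",
            RuntimeWarning,
            stacklevel=2,
        )
        V_new = floor
    return float(pf.U_inv(V_new)), False
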