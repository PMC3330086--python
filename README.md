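# synchain

Event-driven simulation and Markov-chain theory of synchrony propagation in
sparse random networks of leaky integrate-and-fire (LIF) neurons whose
excitatory inputs combine **supra-additively** through fast dendritic spikes.

## The scientific problem

Cortical recordings show spike patterns timed at millisecond precision, yet
purely random networks with linear (additive) synaptic summation cannot
sustain them: a synchronous group of neurons excites, on average, a smaller
group one synaptic delay later, and the chain dies within a few steps —
persistent synchrony classically requires embedded feed-forward structure
(synfire chains).  Fast dendritic sodium spikes change this picture: EPSPs
arriving *simultaneously* at a dendrite are amplified supra-additively and
saturate, while asynchronous inputs and IPSPs sum linearly.  `synchain`
implements a minimal model of this mechanism and the quantitative theory of
when synchronous spiking propagates persistently through a network with **no
structure beyond Erdős–Rényi randomness**.

## Model and theory

Each of N neurons obeys LIF dynamics
`dV/dt = −γV + I_ext + synaptic deltas`, with supra-threshold drive
(`I_ext > γV_Θ`), threshold `V_Θ = 1`, reset `V_r = 0`, and a homogeneous
transmission delay τ.  A directed Erdős–Rényi graph (connection probability
p) carries per-connection signs: excitatory strength ε_exc with probability
p_exc, inhibitory ε_inh otherwise.  Synchronously arriving excitation is
passed through the dendritic modulation function σ — identity below Θ_b,
saturation at s_sat above Θ_s, linear in between — then inhibition is added:
`λ = σ(Σ ε_exc) + Σ ε_inh`.  Simulation is exact and event-driven in the
phase representation `U(φ) = (I_ext/γ)(1 − e^{−γφ}) + V_r e^{−γφ}`, with
inputs applied through `H_λ(φ) = U⁻¹(U(φ) + λ)`.

The sizes g₀, g₁, … of the synchronous groups spiking at t₀ + kτ form
(approximately) a Markov chain: each of the N − g non-refractory neurons
fires independently with probability

    p(g) = Σ_{m,l} P(m, l | g) · F( σ(m·ε_exc) + l·ε_inh ),

where (m, l) is trinomial in the topology statistics and F(λ) is the right
cumulative of the stationary membrane-potential density (diffusion
approximation + Siegert rate, or measured directly in simulation).  Hence

    P(g′ | g) = Binomial(g′; N − g, p(g)),     Ê(g) = (N − g) · p(g).

Intersections of Ê with the diagonal give the fixed points ψ₋ < ψ₀ < ψ₊:
with supra-additive coupling a stable ψ₊ appears above an unstable ignition
threshold ψ₀ — persistent propagation — while the linear network has only the
low absorbing point and every chain decays.

## Worked example

```python
from synchain import (nonlinear_ref, build_network, self_consistent_rate,
    stationary_density_diffusion, build_transition_model, find_fixed_points,
    equilibrate, StimulusProtocol, extract_chain, background_pulses,
    classify_run)
from synchain.simulate import SpikeRaster, advance

params, mod = nonlinear_ref()            # calibrated N = 2000 reference
nu = self_consistent_rate(params, mod)   # background rate, diffusion theory
dens = stationary_density_diffusion(params, nu, mod)
model = build_transition_model(params, mod, dens)
fps = find_fixed_points(model.E_curve)
print(f"background rate nu = {nu:.3f} spikes per membrane time constant")
print(f"fixed points: psi_minus = {fps.psi_minus:.0f}, "
      f"psi_zero = {fps.psi_zero:.1f}, psi_plus = {fps.psi_plus:.1f}")

net = build_network(params, seed=1)
state = equilibrate(params, net, mod, t_eq=10.0, seed=2)
pre, state = advance(state, params, net, mod, 5.0)
t0 = state.t_now
stim = StimulusProtocol.single(t0, g0=190, N=params.N, seed=3)
post, _ = advance(state, params, net, mod, 7.0, stim=stim)
raster = SpikeRaster.concat([pre, post])
chain = extract_chain(raster, t0, params.tau, horizon=69)
bg = background_pulses(raster, chain, (t0 - 5.0, t0 + 7.0))
label = classify_run(chain, bg, bg, f_max=0.1, K_min=20, N=params.N)
print(f"chain sizes g_0..g_10: {chain.sizes[:11].tolist()}")
print(f"largest background pulse: {bg.max_size} neurons -> {label}")
```

prints

```
background rate nu = 0.949 spikes per membrane time constant
fixed points: psi_minus = 0, psi_zero = 95.7, psi_plus = 289.5
chain sizes g_0..g_10: [190, 303, 283, 264, 314, 289, 286, 285, 297, 290, 303]
largest background pulse: 18 neurons -> stable_propagation
```

A pulse of 190 neurons (inside the basin (ψ₀, ψ₊]) ignites a chain whose
groups fluctuate around ψ₊ ≈ 290, far above the spontaneous coincidence
level of ~18 neurons: persistent propagation of synchrony.  Running the same
protocol with `linear_ref()` makes the chain collapse to zero within a few
steps.  The `synchain` command-line tool exposes the same pipelines
(`synchain simulate|theory|scan|calibrate|fixtures`); configs are YAML with
fixture defaults (see `docs/methods.md`).

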