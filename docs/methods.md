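# Methods

## Model

Neurons are leaky integrate-and-fire units, `dV_i/dt = −γ V_i + I_ext`,
between synaptic events, with threshold `V_Θ = 1`, reset `V_r = 0`, and a
constant supra-threshold drive `I_ext > γ V_Θ` that makes every neuron fire
"imprecisely" (quasi-periodically, period `T_free = γ⁻¹ ln[(I_ext − γV_r)/
(I_ext − γV_Θ)]`) even without input.  Synapses are delta pulses delivered a
fixed delay τ after emission.  Connectivity is a directed Erdős–Rényi graph
over ordered pairs (self-connections excluded): each pair carries a synapse
with probability `p_conn`, and each realized synapse is independently
excitatory (`ε_exc > 0`, probability `p_exc`) or inhibitory (`ε_inh < 0`) —
sign per connection, not per neuron.

The single nonlinearity is the dendritic modulation function σ applied to the
summed strength x of *simultaneously arriving* excitatory inputs: σ(x) = x
for x ≤ Θ_b, σ(x) = s_sat for x ≥ Θ_s, affine in between.  It models the
supra-additive amplification and saturation produced by fast dendritic sodium
spikes; because those require coincident input, asynchronous EPSPs (and all
IPSPs, which sum linearly at any time) are unaffected.  The total input of a
wave is `λ = σ(Σ exc) + Σ inh`; inhibition never passes through σ, including
when both signs arrive in the same wave.

## Event-driven simulation

Simulation is exact (no time stepping) in the phase representation
`U(φ) = (I_ext/γ)(1 − e^{−γφ}) + V_r e^{−γφ}`, where the phase advances with
unit slope between events and inputs act through `H_λ(φ) = U⁻¹(U(φ) + λ)`.
The state is the per-neuron *pseudo-spike time* (absolute time of the next
free crossing) plus a FIFO queue of spikes in transit; since τ is homogeneous
the queue is generated already sorted.  Each step processes the earlier of
the next free crossing and the next arrival:

* coincident free crossings (within tolerance `1e−9 τ`) emit together;
* all spikes with one arrival time form one wave; the synchronous update uses
  every neuron's pre-delivery phase, and neurons lifted to or above threshold
  (`≥` convention, overshoot discarded on reset) spike at the arrival time,
  their spikes joining the same outgoing wave τ later;
* external stimuli force immediate spiking of their target set and are
  processed between crossings and deliveries at coincident instants; a neuron
  never spikes twice at one instant.

Potentials may fall below reset (negative phases, same closed form); they are
clamped only at `−I_ext/γ` (counted, never observed with the shipped
parameters).  A guard aborts when the spike rate exceeds 25 times the free
rate per neuron, signalling unstable background; analysis code maps such
aborts to the background-instability labels.  Initial conditions draw phases
uniformly on `[0, φ_Θ)` and place `N·p_conn` random spikes in transit
(configurable); equilibration then runs the network for `t_eq` (default 50
membrane time constants in configs; the validation battery uses 10, which the
stationarity test shows is ample at these parameters).  Given identical seeds
and configuration the raster is bit-identical.  The inner loop is compiled
with numba; a pure-NumPy reference implementation of the wave update
(`deliver_wave`) is kept and tested against the kernel.

## Group-size theory

Chains are read off the raster at the grid t₀ + kτ: the delay is homogeneous,
so chain members spike exactly on the grid while background spikes fall off
it.  Approximating the group sizes as a Markov chain (assumptions: one-step
memory; the background statistics are unchanged by propagation; the g
previous senders are refractory while the other N − g neurons are
equilibrated) gives `P(g′|g) = Binomial(g′; N − g, p(g))` with

    p(g) = Σ_{m,l} P(m, l | g) · F(σ(m ε_exc) + l ε_inh),

(m, l) trinomial with per-sender probabilities (p_conn·p_exc, p_conn·p_inh).
F(λ) is the mass of the stationary membrane-potential density within λ of
threshold.  Two pathways supply that density:

* **diffusion**: background input is treated as Poissonian shot noise with
  drift `μ(ν) = I_ext + νNp(p_exc σ(ε_exc) + p_inh ε_inh)` and diffusion
  `σ_w²(ν) = νNp(p_exc σ(ε_exc)² + p_inh ε_inh²)`; the rate solves
  ν = Siegert(μ(ν), σ_w²(ν)) by bracketing + Brent iteration (rel. tol 1e−8,
  erfcx-stabilized quadrature), and P(V) is the standard stationary
  Fokker–Planck solution with absorbing threshold and re-injection at reset,
  evaluated with Dawson-function exponent differences on ≥ 2000 grid points
  spanning 10·max(σ_w/√γ, V_Θ−V_r) below threshold.  At σ_w = 0 the
  degenerate branch is the deterministic-flow occupancy
  `1/(T_free (I_ext − γV))` on [V_r, V_Θ].
* **semi-analytic**: P(V) is a normalized histogram of membrane potentials
  sampled from equilibrated simulations, eliminating the diffusion and
  mean-connectivity approximations.

p(g) is an exact trinomial sum for g ≤ 300 and, beyond, restricted to the
1e−12 quantile bulk of the count marginals — exact to ~1e−11 at any N (we
prefer this over a normal approximation of the trinomial: same cost, no
approximation error).  Fixed points of the piecewise-linearly interpolated
Ê(g) = (N−g)p(g) are located by per-segment linear solves; stability is
|slope| < 1, slopes within 1e−9 of magnitude 1 are flagged marginal rather
than classified.  The deterministic map iterates `g ← round(Ê(g))`
(round-half-up, documented because fixed points are real-valued) and detects
periodic orbits up to period 8; the stochastic map samples the binomial
kernel with 0 absorbing.

## Classification and scans

A run is classified from one protocol: equilibrate, observe background
(`pre_window`), stimulate g₀ neurons (uniform random subset by default;
index-prefix mode available), follow the chain, observe background again.
Background is unstable if any non-chain coincidence pulse exceeds `f_max·N`
(default f_max = 0.1); propagation is persistent if the first `K_min`
(default 20) chain groups all exceed the largest observed background pulse.
The chain grid is tagged across the *entire* observed window so that a
persistent chain is never mistaken for post-stimulus background.  Scans over
the mean total input strengths `E_tot = Np p_exc ε_exc`,
`I_tot = Np p_inh ε_inh` run `n_nets` independent networks per cell and take
the majority label, ties resolved towards the worst label (bg-pre < bg-post <
unstable-propagation < stable); completed cells persist, making scans
resumable.

## Calibrated fixtures

Structural parameters are fixed at N = 2000, p_conn = 0.05, p_exc = 0.8,
γ = 1 (time in membrane time constants), τ = 0.1, V_Θ = 1, V_r = 0.  The
remaining values were set once by `calibrate_fixtures`, which scans candidate
(I_ext, ε_inh, Θ_b, Θ_s, s_sat) grids and accepts the first candidate whose
diffusion theory yields (i) a background branching ratio Ê(1) ≤ 0.8, (ii)
stable fixed points ψ₋ < ψ₀ < ψ₊ with ψ₊ ≥ 0.02 N, and (iii) no stable fixed
point above the spontaneous level for the same parameters with identity σ.
The accepted values — `I_ext = 1.5` (T_free = ln 3), `ε_exc = 0.0125`,
`ε_inh = −0.05` (mean synaptic drift exactly balanced), `Θ_b = 0.05`
(four coincident EPSPs trigger the dendritic spike), `Θ_s = 0.1`,
`s_sat = 0.3` — are frozen in `fixtures.py` as `nonlinear_ref`
(ψ₀ ≈ 96, ψ₊ ≈ 289) and `linear_ref` (identity σ, decaying map).  Candidates
with larger s_sat produce an upper crossing with slope < −1 (a period-2
band rather than a stable point) and are rejected by predicate (ii).

## What the validation battery does and does not show

The experiments in `synchain.validation` (shared by the test suite and
`scripts/acceptance.py`) use 20 seeds × 50 chain steps for the survival
dichotomy, 3 networks × 8 trials × 8 group sizes for Monte-Carlo
transitions, 2000 single-wave trials for the χ² oracle, and 5×5 scan grids
with 3 networks per cell at shortened observation windows — sizes chosen so
the battery completes in minutes on one core while keeping all statistical
bands well separated.  The synthetic networks realize exactly the model's own
assumptions (homogeneous delay, delta synapses, one dendrite per neuron, no
Dale's law, no plasticity); passing therefore validates the implementation
and the internal consistency of the theory, not the biological fidelity of
the model — real circuits have heterogeneous delays, conductance synapses,
distance-dependent topology and multiple dendritic branches, all outside
scope here.

Known quantitative limitation: the diffusion and semi-analytic expectation
curves agree closely in their fixed points and for large groups (≈ 5–10% for
g ≳ 100), but deviate strongly (up to ~60% relative) where Ê is small and
rising steeply.  With synaptic amplitudes (|ε_inh| = 0.05) comparable to the
absorbing boundary layer of the Fokker–Planck solution (σ_w²/(I_ext − γV_Θ)
≈ 0.06), the white-noise approximation suppresses near-threshold mass that
the true finite-amplitude shot-noise process retains, so F(λ) is
underestimated for λ ≲ a few ε.  The semi-analytic pathway exists precisely
to bypass this and is the one validated against direct simulation.

## Configuration schema

YAML/JSON with top-level keys `fixture` (defaults source), `model`
(ModelParams fields), `modulation` (theta_b, theta_s, s_sat, linear),
`protocol` (t_eq, pre_window, post_window, horizon, g0, n_transit_init,
stim_prefix), `analysis` (f_max, K_min), `seed`.  Unknown keys are rejected;
all outputs embed a SHA-256 hash of the canonical config.
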