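# Methods

## Model

`stplearn` simulates recurrent networks of conductance-based
integrate-and-fire neurons whose synapses combine three plasticity
mechanisms operating on different time scales:

1. **Short-term plasticity (STP)** in the Tsodyks–Markram form.  Each
   synapse j→i carries a depression variable r (available resources) and a
   facilitation variable u (utilization),

       dr/dt = (1 − r)/τ_rec − r·u·δ(t − t_spike),
       du/dt = (U − u)/τ_facil + U(1 − u)·δ(t − t_spike),

   with per-synapse parameters U ∈ [0.05, 0.95], τ_rec ∈ [100, 900] ms and
   τ_facil ∈ [1, 900] ms.  The per-spike release r·u times the maximum
   strength A gives the effective efficacy w = r·u·A.

2. **Triplet STDP** with hard bounds A ∈ [10⁻³, 1].  Four exponential spike
   traces per neuron (fast/slow, pre/post) make potentiation
   frequency-dependent: at high rates the slow postsynaptic trace o2 turns
   the rule Hebbian (co-active neurons strengthen both directions); at low
   rates it reduces to the classical pair rule, which combined with a
   wave-ordered stimulus favors the forward direction and depresses the
   backward one.

3. **Error-driven STP learning.**  Each population holds a target rate
   ν_targ and minimizes E = ((ν_targ − ⟨ν⟩)/ν_lim)², with ⟨ν⟩ the
   population-mean EMA rate estimate (τ_ν = 1 s) and ν_lim = 100 Hz the
   refractory ceiling.  Descending E through the mean-field rate ceiling
   ⟨ν⟩ ≤ A/τ_rec + I_ext (and its heuristic U- and τ_facil-analogues) gives
   per-spike updates that each spiking neuron applies to its *incoming*
   synapses — a target-specific mechanism:

       Δτ_rec  ∝ −(ν_targ − ⟨ν⟩)·A/τ_rec²,   ΔU ∝ −(ν_targ − ⟨ν⟩)·A/U²,
       Δτ_facil ∝ +(ν_targ − ⟨ν⟩)·A,          ΔA ∝ +(ν_targ − ⟨ν⟩)/τ_rec,

   with an error-dependent shared learning rate
   η = η̄(1 + (ν_targ − ⟨ν⟩)/ν_lim)², η̄ = 0.1, and the fixed STDP rate γ
   for the ΔA term.  A scheme name selects which parameters actually move
   (`U_taurec`, `U_taurec_A`, `full`, `taurec_A`, `U_A`, `none`); frozen
   parameters receive exactly zero.

The neuron model is dV/dt = −g_L·V + Σ_j g_ij(E_rev − V) with E_rev =
30 mV, g_L = 0.1 ms⁻¹, spike threshold 1 mV, reset to 0 and a 10 ms
refractory clamp; conductances decay with τ_g = 10 ms and jump at
presynaptic spikes.

## Units and calibration constants

Two scale constants are not fixed by the model's canonical constants and
are exposed explicitly:

* **Learning-update units** (`update_scale`, default 5).  Inside the update
  rules rates are in Hz and time constants in seconds, and deltas are
  converted back to ms.  This yields per-spike τ_rec steps of a few ms and
  U steps of order 10⁻² — adaptation over seconds to tens of seconds,
  matching the fast closed-loop rate convergence the model is meant to
  produce.  The factor applies only to the three dimensionful STP-parameter
  rules; the strength rule's rate is pinned to the STDP rate (η_A ≡ γ), a
  fixed relation of the model.

* **Conductance coupling** (`coupling`, default 0.32/N): the conductance
  injected per unit of released efficacy, g += coupling·r·u·A, with 1/N
  synaptic scaling so the mean recurrent drive is invariant to network
  size.  With the membrane constants above, a unit efficacy produces an
  enormous EPSP (~300× threshold), which drives every neuron to the
  refractory ceiling where triplet LTP locks all weights at A_max and the
  rate error can never be reduced.  The default places the summed
  recurrent drive in the graded regime: the random initial network fires
  (so the spike-triggered learning loop engages), and the firing rate
  responds smoothly to the STP variables and maximum strengths over their
  whole admissible range, in both network architectures.  Both constants
  were calibrated once against that qualitative requirement and are not
  adjusted per experiment.

## Stimulus

The N_in input neurons receive suprathreshold 2 mV pulses in a fixed cyclic
order with lag t_delay = 1/(ν_in·N_in), ν_in = 10 Hz, plus Gaussian jitter
with SD = 0.1·t_delay; jitter draws that would invert the order are
resampled, so the wave ordering is exact.  A pulse arriving during a
refractory period is absorbed.  Input neurons therefore fire at ≥ 10 Hz and
participate in learning with their population's own target and mean.

## Scenarios

* **Single population** (N = 40, all-to-all): 30 input + 10 output neurons;
  the target alternates low (5 Hz) → high (30 Hz) → low → high in phases of
  500 s (configurable), with γ = 2 in low and γ = 1 in high phases.
* **Double population** (N = 80): two mirrored branches with weak lateral
  input–input and output–output connections (initial A ∈ [10⁻³, 0.1]) and
  no cross connections; branch 1 targets 30 Hz, branch 2 targets 5 Hz,
  γ = 2, both targets fixed for the whole run.

## Numerical choices

* Explicit Euler at dt = 1 ms for V and for the continuous STP relaxation
  (stable for τ ≥ dt; the admissible bounds guarantee this); exact
  exponential factors for conductance, trace and rate-EMA decay.
* Per-step order: stimulus pulses → decays → membrane step (refractory
  clamp) → threshold detection → STP release and conductance injection →
  rate impulse → STDP and STP learning per spiking neuron → trace
  increments → recording.  A spike emitted at step t affects other
  membranes from step t+1 (one-step transmission delay).
* Simultaneous spikes are processed sequentially in neuron-index order; all
  trace reads use post-decay, pre-increment values, so a partner spiking in
  the same step contributes nothing to this step's STDP (consistent with
  the strict-ordering pair-rule limit).
* The facilitation increment is applied before the release by default (the
  network's spike-update convention); single-synapse traces default to
  release-then-facilitate so that the first pulse from rest releases
  exactly U, the canonical paired-pulse convention.  Both are switchable.
* Parameters are clipped to their hard bounds after every update; the STDP
  and error-driven contributions to A are summed before a single clip.
* The rate estimate adds 1/τ_ν (in Hz, τ_ν in s) per spike, so steady
  firing at f Hz estimates f Hz.
* RNG streams for initialization and stimulus jitter are spawned separately
  from the master seed, so changing the learning scheme or schedule does
  not shift unrelated draws; identical seeds give bit-identical runs.

## Analysis

The symmetry index of a weight matrix,
s = 1 − [2/(N(N−1) − 2M)]·Σ_{i<j}|A_ij − A_ji|/(A_ij + A_ji), is 1 for
reciprocal and →0 for one-way connectivity; M counts mutually absent pairs
(always 0 here because A ≥ 10⁻³).  Under iid uniform weights the pair terms
have mean 2 ln 2 − 1, so the null mean of s is 2 − 2 ln 2 ≈ 0.6137.  The
null variance is estimated by Monte Carlo and p-values use a normal
approximation; they reproduce order-of-magnitude verdicts, not exact
analytic tail values.  Projection-group summaries report mean ± SD of the
STP parameters per source×target group, with the τ_rec/τ_facil ratio and
the E1/E1a/E1b/E2/E2a/E2b subtype labels assigned by target (E1* onto the
high-rate population, E2* onto the low-rate one).

## What the simulations do and do not show

All inputs are generated internally (wave stimulus, random initial
parameters); there is no external data.  Passing experiments show that the
implemented learning scheme regulates population rates to their targets and
differentiates synaptic parameters by postsynaptic target under the stated
stimulus and constants.  They do not show robustness to other stimulus
statistics (Poisson or naturalistic input), to inhibition (absent here), or
to neuron models with a realistic spike mechanism; and absolute parameter
values depend on the two calibration constants above.

## Known limitations

* At low target rates the output population tends to fire in short
  refractory-locked burst episodes rather than asynchronously; the triplet
  rule then sees high instantaneous rates, which biases the low-rate
  connectivity toward higher symmetry than a fully asynchronous regime
  would produce.
* The mean-field module is a validation surface for the learning-rule signs
  and limits, not a quantitative match to the network.
* The symmetry test's p-values come from Monte-Carlo null moments with a
  normal approximation; exact far-tail values would require the analytic
  null variance, so the test is meant for significant/non-significant
  verdicts, not precise tail probabilities.
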