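# stplearn

Error-driven learning of short-term synaptic plasticity in recurrent
spiking networks.

## The problem

Cortical microcircuits are wired non-randomly: neuron pairs connected by
short-term *facilitating* synapses are over-representedly *bidirectional*,
while pairs connected by *depressing* synapses are mostly *unidirectional*,
and the short-term profile of a synapse correlates with its postsynaptic
target.  `stplearn` implements a model in which these correspondences
*emerge from learning*: the parameters of the Tsodyks–Markram short-term
plasticity (STP) model — utilization U, recovery time constant τ_rec,
facilitation time constant τ_facil — and the maximum synaptic strengths A
adapt online so that each neuronal population reaches a task-defined firing
rate.  The package is for computational neuroscientists who want to
simulate, ablate and analyze this mechanism.

## The model in brief

Conductance-based integrate-and-fire neurons (threshold 1 mV, refractory
10 ms, so rates are bounded by ν_lim = 100 Hz) are coupled by synapses with
effective efficacy w = r·u·A, where r, u follow the TM kinetics

    dr/dt = (1−r)/τ_rec − r·u·δ(t−t_sp),   du/dt = (U−u)/τ_facil + U(1−u)·δ(t−t_sp),

and A follows (i) a triplet STDP rule with hard bounds A ∈ [10⁻³, 1] whose
potentiation is frequency-dependent, and (ii) an error-driven term.  Each
population minimizes E = ((ν_targ − ⟨ν⟩)/ν_lim)²; gradient descent through
the mean-field rate ceiling ⟨ν⟩ ≤ A/τ_rec + I_ext gives per-spike,
target-specific updates applied by each spiking neuron to its incoming
synapses, e.g.

    Δτ_rec = −2η(ν_targ−⟨ν⟩)·A/(ν_lim²τ_rec²),   ΔA = 2γ(ν_targ−⟨ν⟩)/(ν_lim²τ_rec).

Populations driven to a high target develop facilitating synapses (low
τ_rec, U) and bidirectional motifs; populations held at a low target
develop depressing synapses and one-way motifs.  Connectivity is scored by
the symmetry index s ∈ [0, 1] (1 = reciprocal; iid-random weights give
s = 2 − 2 ln 2 ≈ 0.614).

## Worked example

```sh
python examples/double_population.py
```

builds two mirrored 40-neuron branches sharing one sequential-wave input,
assigns branch 1 a 30 Hz target and branch 2 a 5 Hz target, runs the full
learning scheme for 100 s and prints:

```
final output rates (targets 30 / 5 Hz):
  out1:  30.72 Hz   out2:   5.16 Hz

projection-group summary (output-to-output synapses):
          group subtype  tau_rec_ms  tau_facil_ms    U  ratio
out1+out2->out1      E1      348.32        516.71 0.39   0.67
     out1->out1     E1a      329.72        512.42 0.34   0.64
     out2->out1     E1b      365.07        520.56 0.44   0.70
out1+out2->out2      E2      529.78        447.66 0.52   1.18
     out2->out2     E2a      507.37        465.15 0.53   1.09
     out1->out2     E2b      549.95        431.93 0.50   1.27
```

Both populations approach their targets, and the synapses *onto* the
high-rate outputs end facilitating (τ_rec/τ_facil < 1, subtype E1) while
those onto the low-rate outputs end depressing (ratio > 1, E2) — the
postsynaptic target, not the source, determines the synaptic type.  Other
examples: `single_population.py` (alternating low/high targets with motif
switching), `synapse_traces.py`, `symmetry_null.py`, `meanfield_scan.py`.

A thin CLI wraps the same library:

```sh
stplearn run --scenario single --scheme U_taurec_A --seed 1 --outdir run1
stplearn trace --u 0.27 --tau-rec 310 --tau-facil 733 --rate 12
stplearn analyze run1/state.npz
stplearn meanfield --a-syn 0.8 --tau-rec 0.4
```

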