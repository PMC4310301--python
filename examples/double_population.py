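"""Double-population task: target-specific synaptic subtypes.

Two mirrored 40-neuron branches share one input wave; branch 1 must fire at
30 Hz, branch 2 at 5 Hz.  With the full learning scheme the synapses onto
the high-rate outputs become facilitating (low tau_rec, U) and those onto
the low-rate outputs depressing, reproducing an E1/E2-style subdivision by
target.  A short 100 s run is used here; the full experiment runs >= 200 s.
"""

import stplearn as sl

spec = sl.double_population()
state = sl.build_network(spec, seed=42)
cfg = sl.LearningConfig(scheme="full", gamma=2.0)
phases = sl.double_phase_schedule(duration_s=100.0)

result = sl.run_simulation(state, phases, cfg)

print("final output rates (targets 30 / 5 Hz):")
print(f"  out1: {result.rates['out1'].iloc[-1]:6.2f} Hz"
      f"   out2: {result.rates['out2'].iloc[-1]:6.2f} Hz")

table = sl.double_population_table(state.stp_params, spec.mask, spec.populations)
cols = ["group", "subtype", "tau_rec_ms", "tau_facil_ms", "U", "ratio"]
print("\nprojection-group summary (output-to-output synapses):")
print(table[cols].to_string(index=False, float_format=lambda x: f"{x:.2f}"))

print(
    "\nGroups onto out1 (E1*) end with smaller tau_rec/tau_facil ratios than"
    "\ngroups onto out2 (E2*): the postsynaptic target, not the source,"
    "\ndetermines the synaptic type."
)
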