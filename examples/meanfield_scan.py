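"""Mean-field fixed point and the firing-rate ceiling A/tau_rec + I_ext.

Evaluates the equilibrium current F(nu) of a recurrently connected
population with dynamic synapses and shows that its high-rate limit is the
ceiling that the tau_rec learning rule descends.
"""

import numpy as np

from stplearn.meanfield import MeanFieldParams, fixed_point_F, rate_bound

p = MeanFieldParams(A=0.8, U=0.3, tau_rec=0.4, tau_facil=0.6, I_ext=0.1)

print("nu (Hz)   F(nu)")
for nu in np.logspace(0, 3, 7):
    print(f"{nu:8.1f}  {fixed_point_F(p, nu):.5f}")

print(f"\nceiling A/tau_rec + I_ext = {rate_bound(p):.5f}")
print("F(nu) saturates at the ceiling: lowering tau_rec raises the highest")
print("rate the population can sustain, which is why the error-driven rule")
print("moves tau_rec down when the population fires below its target.")
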