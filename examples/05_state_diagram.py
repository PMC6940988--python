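"""Analytic state-diagram sweep over the number of added platelets.

Emits one row per platelet count with the stoichiometric charge-ratio
beta; in dynamics mode (slower) the same sweep also fills beta_c, <N>,
Rg/Rg0, the d-spacing and a shape label from reduced-scale runs.
"""

from tactoid.sweep import sweep_state_diagram

table = sweep_state_diagram("S.I", np_range=range(1, 17), mode="analytic")
print(table[["np", "beta"]].to_string(index=False))
print("beta = Np * 55 / 440; the complex charge-matches the chain at Np = 8")
print("run with mode='dynamics' (and reduced sizes) to fill the other columns")
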