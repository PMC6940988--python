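"""Build the charged platelet, a chain, and an electroneutral system.

Prints the platelet charge anisotropy (face/rim/net), the counterion
bookkeeping, and the stoichiometric charge-ratio beta for the reference
composition: beta = 1 means the chain charge exactly balances the net
charge of the added platelets.
"""

from tactoid import assemble_system, build_nanoplatelet, stoichiometric_ratio

platelet = build_nanoplatelet()
print(f"platelet: {platelet.n_sites} sites, "
      f"Zface={platelet.face_charge_total:+.0f}, "
      f"Zrim={platelet.rim_charge_total:+.0f}, "
      f"Zp={platelet.net_charge:+.0f}")

spec, state = assemble_system("S.I", n_nps=2, n_beads=110, box_length=30.0, seed=0)
print(f"assembled {spec.variant}: {state.n_particles} particles "
      f"({spec.counterion_counts['cation']} cations, "
      f"{spec.counterion_counts['anion']} anions), "
      f"total charge = {state.total_charge:+.0f} e")

for n_p in (4, 8, 12, 16):
    beta = stoichiometric_ratio(n_p, platelet.net_charge, 440, 1.0)
    print(f"Np={n_p:2d}, Nb=440, Zb=1  ->  beta = {beta:.2f}")
# beta crosses 1.0 at Np=8: above that the platelet charge outweighs the chain
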