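"""Enumerate the seven candidate Itk/IP4/PIP3 reaction networks.

Each model is an explicit mass-action network over Itk occupancy states
(dimers carry two PH-domain sites, monomers one) plus the PIP3, IP4 and
PIP2 pools.  The printed counts show how the model classes differ: the
allosteric dimer models carry five rate constants (the high-affinity
off-rate is tied to the K_D ratio alpha), the monomeric feedback model
four, and the no-feedback models three.
"""

import itkmaxent as im

for m in im.MODEL_IDS:
    spec = im.build_model(m)
    kind = "dimer" if len(spec.itk_species) > 3 else "monomer"
    print(
        f"{m}: {kind:7s} {len(spec.itk_species)} Itk states, "
        f"{len(spec.reactions):2d} reactions, "
        f"rates = {', '.join(spec.rate_parameter_names)}"
    )

print("\nM3 catalysis reactions (any PIP3-bound Itk converts PIP2 to IP4):")
for rx in im.build_model("M3").reactions:
    if rx.rate_name == "k_cat":
        print(f"  {' + '.join(rx.reactants)} -> {' + '.join(rx.products)}")
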