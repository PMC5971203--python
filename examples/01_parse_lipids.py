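"""Parse lipid shorthand names and resolve acyl chains.

Lipidomics reports species as sum compositions (total acyl carbons : total
double bonds).  The biophysical models downstream need per-chain structure,
so a deterministic assignment table resolves the split.
"""

from lipidsce import assign_chains, parse_species

for name in ["PE 32:1", "PE 34:2", "PC(C16:0-d31/C18:1)", "TAG 48:2"]:
    sp = parse_species(name)
    resolved = assign_chains(sp)
    chains = "/".join(str(c) for c in resolved.chains)
    std = "  [internal standard]" if sp.is_internal_standard else ""
    print(f"{name:22s} -> class={sp.lipid_class.value:4s} "
          f"{sp.total_carbons}:{sp.total_double_bonds}  chains {chains}{std}")

# The chain split matters because spontaneous curvature and the w weights
# depend on how unsaturation is distributed across chains, which the sum
# composition alone does not state.
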