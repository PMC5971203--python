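# Spontaneous-curvature (C_0) parameter table.
#
# C_0 = 1/R_0, the inverse radius of an unstressed lipid monolayer cylinder
# measured at the pivotal plane; negative for inverse-curvature (type II)
# lipids.  Values here are representative magnitudes assembled from the
# inverse-hexagonal-phase literature for the nearest well-characterised
# species (POPE, DOPE, DOPC, POPS, DOPA, dioleoylglycerol ...), NOT canonical
# constants: published measurements for a given lipid span a factor of ~2
# depending on method, hydration and salt.  Edit freely; every row carries a
# provenance note and downstream results record which row was used.
#
# units: per_nm (converted to 1/m on load) or per_m
# chains: per-chain "C:D" joined by "/" (order irrelevant, multiset match)

bending_modulus_J: 5.0e-20   # monolayer bending modulus K_M, average over lipids
unit: per_nm

entries:
  # --- PC: large zwitterionic head, near-cylindrical, weakly negative C_0
  - {class: PC, chains: 16:0/16:0, c0: -0.02, provenance: "DPPC-like, near zero; interpolated from DOPC/lyso trends"}
  - {class: PC, chains: 16:0/16:1, c0: -0.05, provenance: "interpolated between DPPC and POPC-like values"}
  - {class: PC, chains: 16:0/18:1, c0: -0.06, provenance: "POPC, inverse hexagonal phase X-ray (literature consensus band)"}
  - {class: PC, chains: 16:1/16:1, c0: -0.08, provenance: "di-monounsaturated PC, interpolated toward DOPC"}
  - {class: PC, chains: 16:1/18:1, c0: -0.09, provenance: "interpolated between POPC and DOPC"}
  - {class: PC, chains: 18:1/18:1, c0: -0.11, provenance: "DOPC, X-ray of stressed HII mixtures"}
  # --- PE: small head, strongly type II
  - {class: PE, chains: 16:0/16:0, c0: -0.27, provenance: "DPPE estimate, extrapolated from POPE"}
  - {class: PE, chains: 16:0/16:1, c0: -0.30, provenance: "interpolated POPE-like, shorter sn-2"}
  - {class: PE, chains: 16:0/18:1, c0: -0.32, provenance: "POPE, HII X-ray at pivotal plane"}
  - {class: PE, chains: 16:1/16:1, c0: -0.35, provenance: "di-16:1 PE, interpolated toward DOPE"}
  - {class: PE, chains: 16:1/18:1, c0: -0.37, provenance: "interpolated between POPE and DOPE"}
  - {class: PE, chains: 18:1/18:1, c0: -0.40, provenance: "DOPE, HII X-ray (classic pivotal-plane value)"}
  # --- PS: anionic; headgroup repulsion flattens or inverts curvature
  - {class: PS, chains: 16:0/16:1, c0: 0.06, provenance: "charged-head estimate, low-salt POPS band"}
  - {class: PS, chains: 16:0/18:1, c0: 0.05, provenance: "POPS, osmotic-stress estimate (sign positive at low salt)"}
  - {class: PS, chains: 16:1/16:1, c0: 0.02, provenance: "unsaturation correction applied to POPS"}
  - {class: PS, chains: 16:1/18:1, c0: 0.01, provenance: "unsaturation correction applied to POPS"}
  - {class: PS, chains: 18:1/18:1, c0: 0.01, provenance: "DOPS, near-flat at physiological salt"}
  # --- PA: small anionic head, type II at physiological conditions
  - {class: PA, chains: 16:0/16:1, c0: -0.25, provenance: "interpolated POPA-like"}
  - {class: PA, chains: 16:0/18:1, c0: -0.30, provenance: "POPA, HII mixture extrapolation"}
  - {class: PA, chains: 16:1/18:1, c0: -0.40, provenance: "interpolated toward DOPA"}
  - {class: PA, chains: 18:1/18:1, c0: -0.45, provenance: "DOPA, HII X-ray (pH/salt dependent)"}
  # --- PG: anionic, mildly negative
  - {class: PG, chains: 16:0/18:1, c0: -0.05, provenance: "POPG, near-cylindrical"}
  - {class: PG, chains: 16:1/18:1, c0: -0.08, provenance: "unsaturation correction applied to POPG"}
  # --- DAG: no phosphate head, extreme type II
  - {class: DAG, chains: 16:0/16:1, c0: -0.80, provenance: "scaled from dioleoylglycerol"}
  - {class: DAG, chains: 16:0/18:1, c0: -0.85, provenance: "scaled from dioleoylglycerol"}
  - {class: DAG, chains: 16:1/16:1, c0: -0.90, provenance: "scaled from dioleoylglycerol"}
  - {class: DAG, chains: 16:1/18:1, c0: -0.95, provenance: "dioleoylglycerol band, HII doping experiments"}
  - {class: DAG, chains: 18:1/18:1, c0: -1.00, provenance: "dioleoylglycerol, HII doping experiments"}

# class-level defaults used only when speculative lookups are allowed;
# no measured C_0 exists in the literature for PI.
class_defaults:
  PI: {c0: -0.10, provenance: "speculative: bulky inositol head read as mildly type II"}
  PG: {c0: -0.05, provenance: "speculative class average, POPG-like"}
  DAG: {c0: -0.90, provenance: "speculative class average, dioleoylglycerol band"}
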