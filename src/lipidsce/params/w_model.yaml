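# Coarse-grained w-weight model for the P_SCE ratio control function.
#
#   w(species) = head_term(class) + unsat_increment * (double bonds per chain,
#                summed over chains)
#
# w measures, in a coarse-grained way, how strongly a lipid promotes stored
# curvature elastic stress.  Species with w above the pivot lipid's w are
# type II (stress-raising); w at or below the pivot are type 0.
#
# These coefficients are an editable parameterization constrained by
# qualitative structure-property trends (more unsaturation -> larger w;
# small PE head > large PC head; DAG extreme), NOT values from any published
# calibration.  Use calibrate_w() to refit the increment against low-variance
# reference populations.

head_terms:
  PC: 0.60
  PE: 1.00
  PS: 0.70
  PI: 0.65
  PA: 0.90
  PG: 0.60
  DAG: 1.30
  TAG: 1.20
  LPC: 0.40
  SM: 0.55
  CE: 1.10
unsat_increment: 0.15
pivot: "PE 34:1"
included_classes: [PC, PE, PS, PA, PI, DAG]
denominator_mode: inverse_weight
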