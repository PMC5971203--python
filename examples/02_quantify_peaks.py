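"""Internal-standard quantification: peak areas -> nmol -> mol%.

Simulates integrated LC-MS areas for one synthetic lipidome, inverts them
with the class-matched internal standards, and prints the head-group
composition.  With zero simulated noise the recovery is exact, so the
printed mol% equals the generator's configured t=0 state.
"""

from lipidsce import (
    LipidClass,
    RescueScenario,
    areas_to_amounts,
    class_mol_percent,
    default_standard_config,
    fa_mol_percent,
    generate_peak_table,
    generate_timecourse,
    pc_pe_ratio,
)

scenario = RescueScenario(noise_cv=0.0, n_replicates=1, time_points_h=(0.0,))
samples, _ = generate_timecourse(scenario)
peaks = generate_peak_table(samples, response_noise_cv=0.0)
print(f"peak table: {len(peaks)} rows (incl. internal standards)")

(sample,) = areas_to_amounts(peaks, default_standard_config())
comp = class_mol_percent(sample)
print("choline-starved (t=0) head-group composition, mol% of total lipid:")
for cls, pct in sorted(comp.items(), key=lambda kv: -kv[1]):
    print(f"  {cls.value:4s} {pct:5.1f}")
print(f"PC/PE ratio: {pc_pe_ratio(sample):.3f}  (PC synthesis blocked without choline)")
pe = fa_mol_percent(sample, LipidClass.PE)
print(f"PE 32:1 within PE: {pe['32:1']:.1f} mol% "
      "(saturated species accumulate to blunt the stress of excess PE)")
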