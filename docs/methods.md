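# Methods

## Scope and data model

The pipeline starts at integrated LC-MS peak areas (chromatography, peak
picking and adduct handling are upstream and out of scope) and ends at
per-sample stress metrics with group statistics.  Species are identified
by head-group class and sum composition (total acyl carbons : double
bonds); an optional per-chain annotation carries isotope labels.  Species
with any labelled chain are internal standards: they are used as
quantification references and excluded from every biological composition.
Amounts are nmol per 50 mg biomass throughout; both stress metrics and all
mol% quantities are invariant to uniform rescaling, so this unit choice
only affects absolute-amount displays.

## Quantification

Single-point, one-standard-per-class response model:
`amount = area / area(class standard) × spiked nmol`.  No calibration
curves and no per-species response corrections — exactly what a
class-matched internal standard supports.  Classes without a spiked
standard in the default panel (PS, PI, PA, PG, DAG) are routed to a
surrogate standard (PC for the glycerophospholipids, TAG for DAG); the
mapping is configuration, not constant, and is recorded in output
provenance.  Spiked amounts are required config values in nmol: vendor
sheets state standards as mass concentrations and the molar conversion
depends on the exact species, so no conversion is hard-coded.

## Chain assignment

Measured sum compositions are resolved to per-chain structure by an
explicit table with a deterministic default rule (even carbon split in
steps of two, double bonds spread evenly with the remainder on the longer
chain), which reproduces the common yeast pairs: 32:1 → 16:0/16:1,
34:1 → 16:0/18:1, 34:2 → 16:1/18:1.  This is an implementer convention —
the acyl pairing of a sum composition is not measurable from the data the
pipeline consumes — and both the C0 fallback and the w model consume its
output, so a user with chain-resolved data can override the table and
bypass the convention entirely.

## Lipid SCE stress (tau)

`tau = -2 K_M C0_mix`, with `C0_mix = Σ x_i C0_i` by ideal additive
mixing, generalised from the two-component formula to n components by the
same additivity (the two-component case is recovered exactly and tested).
K_M is a single scalar, 5.0e-20 J, an average over lipids; per-species
bending moduli are out of scope.  Internal unit for C0 is 1/m; the
parameter file may state values in 1/nm with a unit tag.

C0 lookup order: exact match on (class, chain multiset); else among
same-class entries with the identical per-chain double-bond multiset, the
minimal |Δ total carbons| entry, ties broken toward the shorter chain
(deterministic); else, only when a variant allows it, a class-level
default flagged `speculative`.  Every result records the value and match
kind used per species.

The shipped C0 table is a representative parameterization assembled from
inverse-hexagonal-phase literature magnitudes (POPE ≈ -0.32 /nm,
DOPE ≈ -0.40 /nm, DOPC ≈ -0.11 /nm, DOPA ≈ -0.45 /nm, dioleoylglycerol
≈ -1 /nm, weakly positive PS), not canonical constants: published values
for one lipid vary by ~2× with method and conditions.  Conclusions should
rest on trends and contrasts, which are insensitive to the absolute
scale; the table is editable and provenance-annotated per row.

Class-inclusion variants: default {PC, PE, PS, PA, PG}.  PI is excluded
because no measured C0 exists (its variant uses a speculative default);
DAG and TAG are excluded because they partition into lipid droplets
rather than the bilayer.  `sensitivity_analysis` recomputes the mean-tau
series under alternates and flags whether the sign pattern of successive
differences matches the base series.

## P_SCE

`w = head_term(class) + unsat_increment × (double bonds summed over
chains)`; type II iff `w > w(pivot)` with pivot PE(34:1), equality
classed type 0 (the pivot itself is type 0).  `P_SCE = Σ w_n [L_II,n] /
Σ g(w_m) [L_0,m]`.  The denominator weighting is ambiguous in its printed
source form; the default reads it as `g(w) = 1/w` (`inverse_weight`),
with `direct_weight` available as a switch rather than a hard-coded
interpretation.  The summation bounds are read as "over all type II" and
"over all type 0" species.  Included classes default to
{PC, PE, PS, PA, PI, DAG}; TAG (droplet-resident) and PG (no parameters
in the source model) are excluded, both overridable.

The shipped coefficients (PE head 1.0 > PC head 0.6, DAG 1.3, increment
0.15 per double bond) are constrained only by qualitative
structure–property trends and are flagged non-canonical.  `calibrate_w`
refits them by minimising the variance of P_SCE across reference
populations — the selection principle that defined the original weights —
over a finite user-supplied grid, deterministically (ties to the first
candidate).  `generate_calibration_populations` builds a synthetic
testbed for this: populations whose type II and type 0 pools are traded
internally so that P_SCE is exactly constant under the generating
coefficients and scattered under any other increment; parameter-recovery
on it is exercised to within one grid step.

## Synthetic choline-rescue generator

The generator emulates the lipidome dynamics of a choline-rescue
experiment in a strain whose PC synthesis requires exogenous choline:
defaults are PC 2 → 40 mol% of total lipid, PE 45 → 22, PS 8 → 12
(the small starvation decrease), TAG 25 → 6, PI/PA/DAG flat, with
within-class acyl shifts placing PE 32:1 and PS 32:1 at 30 mol% of their
class at t=0, falling as 34:2 rises to compensate.  Time grid
{0, 2, 4, 8, 24} h, 3 replicates, total 200 nmol per 50 mg.  Kinetics are
a single-exponential approach to the post-choline steady state (half-time
4 h) — the simplest form consistent with gradual recovery, not a
mechanistic claim.  Noise is multiplicative lognormal with mean 1
(amounts are positive and replicate spread grows with the mean), CV 0.15
per species, independent across species and replicates.  Class and
within-class targets must each sum to 100; expectations are renormalised
per time point so mixed half-times cannot break the invariant.  The
noise-free expectations are returned alongside the samples as ground
truth.

Simulated peak tables apply a response factor per quantification group
(the class of the standard that quantifies the analyte) times lognormal
response noise; the grouping makes the internal-standard ratio cancel the
factor exactly, mirroring the single-point response model.

What the generator does not emulate: between-replicate correlation
(batch effects), species-level response differences within a class,
censoring at the detection limit, ether lipids and minor classes, and any
mechanistic coupling between classes.  Passing tests therefore show the
pipeline's algebra and trend logic are right under realistic magnitudes
and noise — not that real instrument data would be quantified without
bias.

## Statistics

Pooled-variance (Student) two-sample t tests, two-tailed; one-way ANOVA
omnibus with Bonferroni over all pairwise comparisons (adjusted
p = min(1, raw p × number of pairs); a single pair is uncorrected, where
the omnibus p equals the pooled-t p exactly).  Summaries are mean ± SD.
Significance stars at 0.05/0.01/0.001/0.0001.  ANOVA is computed across
the full time series per condition with per-pair adjustment (whether to
test per time point instead is a design choice; this one is documented in
the report provenance).  Degenerate groups (fewer than two values) are
rejected rather than silently dropped.

## Numerical choices and degenerate inputs

All mol% outputs sum to 100 within 1e-9.  tau is computed as the literal
product `-2 * K_M * C0_mix`, so the identity holds bit-for-bit on every
result.  Zero or missing standard areas, all-zero included compositions,
empty inclusion sets, zero-PE PC/PE ratios, and zero-type-0 P_SCE
denominators raise typed errors naming the offending sample/class; the
class enumeration is closed and unknown codes fail at parse time.  The
problem sizes exercised by the test suite and acceptance script (15–200
samples, 1000-fold oracle and null simulations) were chosen to make every
stochastic check stable at fixed seeds while keeping a full run in the
order of seconds.

## Known limitations

- Absolute tau values inherit the C0 table's uncertainty; only trends are
  robust.  Leaflet asymmetry, curvature–composition coupling beyond
  linear mixing, and per-species K_M are not modelled.
- The w coefficients are a stand-in parameterization; P_SCE levels (as
  opposed to its stability) should not be compared across studies without
  recalibration.
- Sphingomyelin is treated as a two-chain species at sum-composition
  level; sphingoid-base notation is not parsed.
- The chain-assignment convention is untestable from sum-composition
  data; chain-resolved inputs bypass it.
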