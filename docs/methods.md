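# Methods

## The measurement model

An in-situ ¹⁵N pulse-labeling experiment marks one soil N pool (NH₄⁺ or
NO₃⁻) around a single plant and reads the tracer back in whole-plant tissue
after a fixed incubation. The analysis chain assumes:

- **Linear uptake over the incubation window.** Uptake rates are tracer
  uptake divided by (root biomass × time); no growth or pool turnover
  dynamics inside the 48 h default window are modeled. Nitrification of the
  NH₄⁺ label is assumed fully suppressed (the field protocol this emulates
  applies a nitrification inhibitor), and isotope-dilution corrections for
  gross mineralization are out of scope.
- **Tracer equivalence.** The plant takes up added ¹⁵N and pre-existing
  soil N in proportion to their amounts per kg of soil, so actual uptake =
  tracer uptake × C_available/C¹⁵N_added, per form.
- **Whole-plant pooling.** Atom% and N concentration refer to one
  mass-weighted whole-plant sample; `pool_shoot_root` converts separate
  shoot/root analyses to that basis when needed.
- **Baseline cancellation.** Atom% excess is the labeled plant minus its
  same-quadrat, same-species control; the atmospheric standard cancels in
  the subtraction. Negative excesses (possible under measurement noise) are
  clamped to zero but counted and flagged (`ape_clamped`), since silently
  hiding them would mask QC problems.

`C¹⁵N_added` is derived from nominal geometry — dose / (π r² h ρ_b) — with
bulk density defaulting to 1.273 g cm⁻³ so the default 5 cm × 15 cm cylinder
holds ≈ 1500 g of soil and receives ≈ 0.240 mg ¹⁵N kg⁻¹. Whether a field
study computed it from nominal geometry or per-sample soil mass is rarely
stated; all three constants are config knobs.

One printed-formula note: the widely circulated shorthand for tracer uptake,
"APE × biomass × N% × 1000", is dimensionally inconsistent by 10× when both
percentages are carried as percent. This package uses the unit-consistent
form (APE/100)·biomass·(N%/100)·10⁶ μg throughout.

## Strategy indices

f is computed from actual uptake **rates**, pairing the two labeled
individuals of a quadrat. Rates (not amounts) are authoritative because the
NH₄⁺- and NO₃⁻-labeled plants are distinct individuals with different root
biomasses; rate normalisation removes that nuisance difference. Soil
proportions p default to the mean of the two labeled plants' own rhizosphere
measurements (`soil_source="plant_pair"`); `"quadrat"` additionally includes
the control plant's soil record. Quadrat pairs with a missing member, zero
total rate or empty soil DIN are flagged `excluded` and dropped from
aggregation rather than erroring.

PS is computed per quadrat pair and then averaged (n = 12 per species ×
habitat cell in the default design); computing it on cell means instead is
possible via `aggregate_indices` on f and p, but the per-quadrat form is the
primary one. PS, β and f obey exact identities (f pair sums to 1, β pair
sums to 0, PS = 100 − 100·|β_NH4|) that the pipeline asserts in tests.

## The simulator and what it does (not) emulate

`simulate_dataset` inverts the analysis chain: per-cell true actual uptake
rates → actual uptake for each plant's drawn root biomass → tracer uptake
via C¹⁵N_added/C_available with that plant's own drawn soil pools → APE →
labeled atom% = baseline + APE → δ¹⁵N. Noise enters as:

- δ¹⁵N: additive normal in δ-space, sd 0.2‰ (typical IRMS analytical
  precision);
- biomass, N concentration, soil pools: mean-preserving log-normal with
  relative sds 0.20, 0.05 and 0.25 — plausible within-cell field
  variability for herbaceous stands, chosen once as round numbers since
  field studies rarely report their variance components.

Per-plant labeled-zone root biomass is a configurable fraction
(`cylinder_root_fraction`, default 0.02) of the quadrat's per-m² root
standing crop: the labeled cylinder covers ≈ 0.8% of a 1 m² quadrat, and
roots concentrate around the target plant, so 2% is a reasonable default;
recovery results do not depend on it because the same drawn value is used
forward and backward.

Because the analysis uses each plant's recorded biomass and soil values, the
only noise source that biases rate recovery is the δ¹⁵N error — which is why
cell-mean recovery under the default design is comfortably within 10%. The
simulator therefore does **not** test robustness to errors the chain cannot
see: soil-pool measurement bias, heterogeneous label distribution in the
cylinder, root-surface ¹⁵N contamination, or site-level random effects
(cells are iid; there is no between-site variance component). Passing
recovery tests show the arithmetic chain is self-consistent and
noise-stable, not that field data meet these assumptions.

The default truth table mirrors a qualitative invasion-ecology pattern —
ammonium-dominant farmland/wasteland soils, nitrate-dominant roadside, an
invader tracking the dominant form, a native preferring nitrate everywhere,
invader biomass larger throughout — with illustrative magnitudes (uptake
rates 0.6–7 μg N g⁻¹ root h⁻¹, pools 2–8 mg N kg⁻¹). It is a synthetic
construct for structural tests, not a reconstruction of any study's values.
The generator refuses truth tables whose implied labeled-plant atom% exceeds
the label enrichment (`InfeasibleLabelingError`): the dose cannot support
the requested uptake.

## Statistics layer

- **Quantile transform**: rank-based inverse normal with Blom offset
  (r − 3/8)/(n + ¼), average ranks for ties; used for bounded indices (β)
  before parametric tests. All-tied input is degenerate and rejected.
- **ANOVA letters**: Tukey HSD p-values feed an insert-and-absorb compact
  letter display; groups share a letter iff their pairwise test is
  non-significant at α. All-zero-variance input returns a single shared
  letter with p = 1 by convention.
- **t-tests**: pooled-variance by default (matching common practice in the
  field literature; Welch via `equal_var=False`). Zero-variance samples with
  equal means return t = 0, p = 1, flagged degenerate.
- **Mixed-model screen**: REML MixedLM with a random site intercept and a
  variance component for quadrats nested in sites; Wald χ² per fixed term.
  Single-site designs or non-convergent/singular fits downgrade to OLS
  ANOVA with a warning and a `method` flag — a deliberate contract, since
  balanced noisy-but-iid data make near-zero variance components common.
- **SMA**: slope = sign(r)·sd(y)/sd(x) through the centroid. The
  common-slope test minimises −Σ(nᵢ − 5/2)·ln(1 − r²ᵢ(B)) over B, where rᵢ
  is the within-group correlation between the residual (y − Bx) and fitted
  (y + Bx) axes; the minimum is asymptotically χ²(g − 1). The nᵢ − 5/2
  weight is the standard small-sample correction; seeded null simulations
  at n = 50 put the empirical size at ≈ 0.055. Elevation (intercepts at the
  common slope) and shift (fitted-axis means) are Wald tests with
  group-variance weights, and are reported only when the common-slope test
  is non-significant at α — a heterogeneous-slopes comparison of
  intercepts is not meaningful. Slope sampling variance uses the
  large-sample form B²(1 − r²)/(n − 2). SMA lines are flagged significant
  for reporting when the underlying correlation test has p < 0.05 (an
  R² > 0.1 screen mirrors common figure-caption practice).
- **Multiple testing**: none across response variables, recorded in the
  report metadata.

Numerical choices: the common-slope optimisation runs in log-slope space
(sign fixed by the pooled correlation) over [min slope/e³, max slope·e³]
with 1e-10 tolerance; percent-valued quantities are stored as percent;
fraction-pair validation uses a 1e-9 sum tolerance.

## Reproducibility

A pipeline run is a pure function of (inputs, config, seed): one
`numpy.random.default_rng(seed)` drives all draws in a fixed order, and
`run_meta.json` records the seed, a SHA-256 hash of the scientific
configuration (output path excluded), and per-artifact SHA-256s. Column
units live in a machine-readable `schema.json` sidecar so the CSVs stay
hand-editable.

## Known limitations

- Two N forms only; the index algebra generalises to organic N (glycine,
  amino acids) but is implemented for the NH₄⁺/NO₃⁻ DIN case.
- No spatial soil heterogeneity, label diffusion, or plant growth dynamics
  within the incubation window.
- Elevation/shift Wald tests ignore common-slope estimation error beyond
  the plug-in variance term; their Type I error is checked by simulation
  only at moderate n.
- The simulator's iid cell structure understates the real design's
  site-level dependence, so mixed-model power figures from synthetic data
  are optimistic for field use.

## Problem sizes in tests

Monte-Carlo checks use 200 replicates of the full 216-plant design for
noisy parameter recovery, 1000 two-group null simulations (n = 50 each) for
common-slope test size, 200 for its power, and 100 noisy replicates for the
qualitative sign-structure check — sizes at which the binomial uncertainty
on each empirical rate is well inside the asserted bands.
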