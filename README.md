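# ntracer

Analysis toolkit for **¹⁵N field-labeling experiments on plant nitrogen-form
acquisition**: which inorganic N form (ammonium or nitrate) a plant takes up,
whether it *prefers* one form beyond its soil availability, and how *plastic*
that choice is across habitats. The package targets paired invasive/native
comparisons across a hierarchical field design (sites × habitats × quadrats),
but every layer works on any tidy plant/soil table.

## Who this is for

Plant ecophysiologists and invasion ecologists running in-situ ¹⁵N tracer
additions: one plant per quadrat labeled with ¹⁵NH₄⁺, one with ¹⁵NO₃⁻, one
untreated control, with rhizosphere soil NH₄⁺/NO₃⁻ pools measured per plant.

## The computation chain

For each labeled plant, with atom% measured by IRMS (δ¹⁵N is converted via
AT% = 100·R/(1+R), R = 0.0036765·(δ/1000 + 1)):

```
APE        = AT%_labeled − AT%_control                      (atom% excess)
¹⁵N_uptake = (APE/100) · total biomass · (N%/100) · 10⁶     (μg)
¹⁵N rate   = ¹⁵N_uptake / (root biomass · time)             (μg g⁻¹ root h⁻¹)
Actual uptake (rate) = ¹⁵N uptake (rate) · C_available / C¹⁵N_added
Uptake per quadrat   = actual rate · root biomass_quadrat · time   (μg m⁻²)
```

`C¹⁵N_added` is the tracer dose divided by the soil mass of the labeled
cylinder (π r² h ρ_b; ≈ 0.240 mg N kg⁻¹ for the default 360 μg dose into
≈ 1500 g of soil). From the paired NH₄⁺-/NO₃⁻-labeled plants of each quadrat:

- **f_NF** — proportional contribution of each form to total actual uptake
  rate, `f_NH4 = rate_NH4 / (rate_NH4 + rate_NO3)`;
- **β_NF** — preference index, `β_NF = f_NF − [NF]/[DIN]` (β > 0: preference);
- **PS** — percentage similarity between uptake and soil compositions,
  `PS = 100·(1 − ½ Σ|f − p|)`; PS = 100% means perfectly proportional
  ("plastic") uptake.

The comparison layer supplies rank-based inverse-normal (Blom) and log
transforms, Shapiro–Wilk/Levene assumption checks, one-way ANOVA with
Tukey-HSD compact letter displays, pooled/Welch and one-sample t-tests
(β vs 0), a mixed-model screen (habitat × species fixed, quadrats nested in
sites random), and **standardized major axis (SMA) regression** with
common-slope likelihood-ratio, elevation and shift-along-axis tests.

A forward simulator generates complete synthetic field datasets from a
ground-truth table of uptake rates, so the whole chain is testable by
parameter recovery: with zero noise the pipeline inverts the simulator
exactly (≤ 1e-10 relative error).

## Worked example

```python
import ntracer as nt

ds  = nt.simulate_dataset(nt.StudyDesign(seed=0))                 # 216 plants
up  = nt.compute_uptake_table(ds.plants, ds.soil, ds.quadrats, nt.LabelingConfig())
idx = nt.compute_indices_table(up, ds.soil)                       # 72 quadrat pairs
print(nt.aggregate_indices(idx)[
    ["species", "habitat", "f_nh4_mean", "beta_nh4_mean", "ps_mean", "ps_se", "ps_n"]
].round(3).to_string(index=False))
```

```
 species   habitat  f_nh4_mean  beta_nh4_mean  ps_mean  ps_se  ps_n
invasive  farmland       0.769          0.098   90.226  1.608    12
invasive  roadside       0.125         -0.064   93.636  1.083    12
invasive wasteland       0.833          0.137   86.332  1.455    12
  native  farmland       0.570         -0.090   90.982  1.251    12
  native  roadside       0.149         -0.045   95.374  1.051    12
  native wasteland       0.533         -0.154   84.597  2.089    12
```

Each row is a species × habitat cell mean over n = 12 quadrats. Under the
default ground truth the invader's uptake tracks the locally dominant form
(β_NH4 > 0 in the ammonium-dominant farmland/wasteland, β_NH4 < 0 — i.e.
nitrate preference — in the nitrate-dominant roadside), while the native
leans on nitrate everywhere; PS near 90% reflects mild preferences on top of
largely proportional uptake.

The same run from a shell:

```bash
ntracer simulate --seed 0 --out data/
ntracer compare --in data/ --out analysis/      # uptake.csv, indices.csv,
                                                # tests.csv, stats_report.json
```

Outputs carry a `run_meta.json` (seed, config hash, artifact SHA-256s) and a
`schema.json` sidecar documenting column units; artifacts are a pure
function of (inputs, config, seed).

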