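# bmquant

Automated whole-body quantification of bone-marrow (BM) metabolism on
[¹⁸F]FDG PET/CT for multiple myeloma, with the downstream prognostic
statistics — built and validated entirely on digital phantoms and simulated
survival cohorts with known ground truth.

## Who this is for

Multiple myeloma infiltrates the bone marrow both diffusely and as focal
lesions; how much of the skeleton is metabolically active is a tumor-burden
surrogate with prognostic meaning. This package is for imaging and
biostatistics researchers who want a reproducible, fully automated version of
that reading chain:

1. **Anatomy** — CT-based skeleton extraction (HU threshold + morphological
   closing), partition into *axial skeleton* (vertebrae, ribs, sternum,
   pelvis, ...) and *extremities* (humeri, femora) with the skull excluded
   (the adjacent brain's physiological uptake would contaminate it), and a
   contractive spillover refinement (erosion + exclusion margin around hot
   organs).
2. **Quantification** — ten SUV-threshold approaches, each pairing an axial
   and an extremity rule built from reference organs (liver SUV median/mean,
   muscle SUV median × 4) or absolute SUV values (2.0, 2.5, 3.0). A voxel is
   pathological when SUV ≥ threshold (inclusive). Per approach:
   **MTV** (mL) = segmented volume, and **TLG** (g) = SUVmean × MTV.
3. **IMPeTUs** — the structured Italian Myeloma criteria for PET Use:
   5-point Deauville score of diffuse lumbar uptake and of the hottest
   lesion, focal and lytic lesion counts binned F1–F4 / L1–L4
   (none / 1–3 / 4–10 / >10), paramedullary (PMD) and extramedullary (EMD)
   disease flags, fractures.
4. **Survival statistics** — Spearman correlation with marrow plasma-cell
   infiltration, Kaplan–Meier with median survival, inverse-KM median
   follow-up, log-rank on median-dichotomized markers, uni-/multivariable Cox
   proportional hazards (Efron ties; Breslow optional), 2-year-outcome ROC
   with the Youden-optimal cut point (DeLong CI), and ISS / R-ISS staging.

Because no patient cohort is distributable, the `synthetic` module generates
seeded PET/CT phantoms (axis-aligned organs, spherical lesions of exactly
known volume, diffuse marrow uptake rising linearly with infiltration) and
survival cohorts drawn from a proportional-hazards model whose hazard depends
on MTV — so every stage can be checked against exact oracles.

## Worked example

```python
import bmquant as bq

cfg = bq.PhantomConfig(noise_sd=0.0, liver_suv=2.0, infiltration_fraction=0.68)
_, suv, truth = bq.generate_phantom(cfg)          # diffuse marrow SUV = 2.5
masks = bq.masks_from_labels(truth.label_map)
for r in bq.quantify_all_approaches(suv, masks):
    print(r.approach_id, round(r.mtv_ml, 1), round(r.tlg_g, 1))
```

prints (approach, MTV mL, TLG g):

```
1 41.4 103.6
2 24.2 60.5
3 41.4 103.6
4 41.4 103.6
5 41.4 103.6
6 41.4 103.6
7 41.4 103.6
8 41.4 103.6
9 41.4 103.6
10 0.0 0.0
```

The diffuse marrow SUV (2.5) sits between the liver median (2.0) and 3.0, so
every approach whose thresholds stay at or below 2.5 captures the whole
analysis skeleton (41.4 mL — skull excluded); approach 2 loses the axial
compartment (liver × 1.5 = 3.0 > 2.5) but its muscle-based extremity rule
(0.6 × 4 = 2.4) still fires; and the absolute-3.0 approach 10 sees nothing
at all — the qualitative behaviour that makes patient-relative liver
cut-offs preferable to absolute SUV rules for diffuse disease.

The numbered drivers under `analysis/` run the full study: `01` builds a
phantom batch (volumes under `scratch/`, truth table under `results/`), `02`
quantifies all ten approaches (Spearman ρ = 0.93 between infiltration and
approach-5 MTV on the batch), `03` emits an IMPeTUs report, `04` simulates a
500-subject cohort (Spearman ρ = 0.46 between MTV and infiltration), and `05`
produces the KM/Cox/ROC tables (univariable HR 1.0011 per mL against a true
1.0012).

A `bmquant` CLI wraps the same steps (`bmquant phantom|quantify|impetus|
survival|study --help`).

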