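# choromel

Quantification of melanin-containing tissue in the choroid from
polarization-sensitive optical coherence tomography (PS-OCT).

## The problem

The choroid — the vascular layer between retina and sclera — is rich in
melanocytes whose melanin absorbs stray light and protects the retina from
oxidative stress. Changes in choroidal melanin accompany several
chorioretinal diseases, but there is no routine in-vivo measure of it:
histology needs enucleated eyes, and standard OCT is blind to pigment.

PS-OCT records the backscattered field in two polarization channels.
Melanin granules scramble polarization, so the *degree of polarization
uniformity* (DOPU) drops wherever melanin is abundant. This package turns
dual-channel PS-OCT volumes into three en-face maps —

* **choroidal thickness** (μm),
* **thickness of melanin-containing tissue in the choroid** ("thickness of
  MeCh", μm): the per-A-line count of low-DOPU pixels inside the choroidal
  interstitial stroma, times the axial pixel size,
* **choroidal melanin occupancy rate**: the fraction of interstitial-stroma
  pixels that are low-DOPU — a melanin density independent of choroidal
  thickness,

— and into fovea-centered sector statistics and cohort-level analyses.
Because no public PS-OCT dataset with ground truth exists, the package
ships a synthetic phantom generator with voxel-level truth, so every stage
is testable end to end.

## The method

For each voxel the Stokes vector is computed from the two complex channels
(H, V):

    I = |H|² + |V|²,  Q = |H|² − |V|²,  U = 2 Re(H V*),  V = −2 Im(H V*),

and averaged over a 3 × 3 pixel kernel within the B-scan (≈ 35 μm lateral
× 13 μm axial at the nominal pitch) after subtracting the additive-noise
bias (n_H, n_V estimated from a signal-free region):

    DOPU = sqrt(Q̄_c² + Ū² + V̄²) / Ī_c,
    Ī_c = mean(I − n_H − n_V),   Q̄_c = mean(Q − n_H + n_V).

Voxels with DOPU < 0.8 are "low-DOPU" (melanin-rich). The choroid is
delineated (bundled heuristic or imported boundaries), split into vessel
lumina and interstitial stroma by per-pixel local Otsu thresholding with
median-filter cleanup, and the three maps are aggregated over a 5-mm disc
centred on the fovea, its 2-mm center, and superior / inferior / nasal /
temporal quadrants of the outer ring. Transverse magnification is
calibrated per eye from axial length AL via the Bennett–Littman factor
q(AL) = 0.01306 (AL − 1.82). The statistics module provides Pearson
correlations, SPSS-style stepwise multiple regression (entry p ≤ 0.05,
removal p ≥ 0.10), exact Wilcoxon signed-rank tests, Friedman tests with
Dunn–Bonferroni post hocs, and coefficients of variation for repeated
scans.

## Worked example

```python
import numpy as np
import choromel as cm

spec = cm.demo_spec(seed=7, rho=0.38)          # 6 x 6 mm field, 128 x 64 A-scans
volume, truth = cm.make_phantom(spec)          # PS-OCT phantom + ground truth

config = cm.RunConfig(eye_id="example", seed=7)
result = cm.run_eye(config, volume=volume)     # DOPU -> masks -> maps -> sectors
print(result.sector_table.round(3).to_string(index=False))

whole = result.sector_table.set_index("sector").loc["whole"]
print(f"recovered whole-area occupancy: {whole['mean_occupancy']:.3f}")
print(f"ground-truth occupancy:         {np.nanmean(truth.occupancy):.3f}")
```

prints

```
    sector  mean_choroidal_thickness_um  mean_mech_thickness_um  mean_occupancy  n_valid_px
     whole                      231.666                  75.384           0.370        4319
    center                      258.757                  71.516           0.318         673
  superior                      227.180                  68.598           0.371         913
  inferior                      227.519                  90.257           0.406         910
     nasal                      226.379                  73.445           0.373         920
  temporal                      225.578                  72.117           0.368         903
outer_ring                      226.666                  76.098           0.380        3646

recovered whole-area occupancy: 0.370
ground-truth occupancy:         0.376
```

The phantom was built with a stroma-conditional melanin fraction of
ρ = 0.38; the full pipeline — noise-corrected DOPU, heuristic choroid
segmentation, local-Otsu stroma binarization, sector aggregation —
recovers a whole-area occupancy of 0.370 against a ground truth of 0.376.
The thickness column reflects the phantom's centrally thickened choroid
(≈ 259 μm in the 2-mm center vs ≈ 227 μm in the outer ring).

The same pipeline runs from the shell:

```sh
choromel simulate --out scratch/vol.raw --seed 7 --rho 0.38
choromel run-all --volume scratch/vol.raw --out scratch/eye --seed 7
choromel cohort-stats --synthetic-n 105 --seed 0
```

## Layout

| module | role |
| --- | --- |
| `choromel.phantom` | synthetic PS-OCT volumes with voxel-level ground truth |
| `choromel.polarimetry` | Stokes vectors, noise-corrected DOPU, low-DOPU mask |
| `choromel.segmentation` | choroid boundaries, Otsu core, vessel/stroma binarization |
| `choromel.metrics` | en-face thickness / MeCh / occupancy maps |
| `choromel.sectors` | magnification calibration, fovea-centered sector grid and means |
| `choromel.stats` | regressions, Wilcoxon / Friedman tests, coefficients of variation |
| `choromel.cohort` | synthetic per-eye cohorts with built-in age/axial-length effects |
| `choromel.pipeline`, `choromel.io`, `choromel.cli` | orchestration, file formats, CLI |

See `docs/methods.md` for the measurement model, the phantom's design and
its limitations, and the numerical choices.
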