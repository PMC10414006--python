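# bbbhotspots

Blood-brain-barrier (BBB) leakage "hotspot" analysis for cerebral small
vessel disease (SVD) DCE-MRI studies, exercised end to end on a synthetic
cohort generator with known ground truth.

In SVD, dynamic contrast-enhanced MRI can quantify subtle BBB leakage as
the permeability surface area product (PS). Rather than averaging PS over
large regions, this package maps *focal* regions of extreme leakage and
asks whether they collocate with the classic SVD lesions — lacunes, white
matter hyperintensities (WMH) and cerebral microbleeds (CMB).

## What it computes

1. **Patlak mapping** — per voxel, the two-parameter graphical model

   C_t(t) = v_P · C_p(t) + PS · ∫₀ᵗ C_p(τ) dτ

   is fitted by ordinary least squares (no intercept, no backflux), giving
   the fractional plasma volume v_P and the leakage rate PS (min⁻¹).
   Negative estimates are legitimate noise outcomes and are never clamped.
2. **Analysis mask** — white matter (NAWM ∪ WMH, brainstem excluded) after
   a one-voxel 3×3×3 erosion.
3. **Hotspots** — connected clusters (26-connectivity) of at least 5 voxels
   whose PS lies in the patient's top decile inside the eroded mask, with
   regional distribution scored on a 0–6 left+right ordinal load scale.
4. **Colocalization** — per hotspot: at a lacune edge, within WMH, at a WMH
   edge, at a CMB edge (contact = overlap with the lesion or its one-voxel
   outer band), with subgroup eligibility rules and cohort summaries.
5. **Statistics** — total SVD score (0–4), linearly weighted kappa,
   descriptive tables, group comparisons, a p<0.1 univariable screen, and
   multivariable logistic / proportional-odds ordinal models for hotspot
   presence and count, with VIF collinearity checks (<5 acceptable).
6. **Synthetic cohorts** — two-arm (sporadic SVD / CADASIL) phantom brains
   with STRIVE-style lesion geometry, spatially structured PS truth with
   planted high-leakage foci, Patlak-consistent DCE series, and covariates
   with configurable planted effects.

## Worked example

```python
import numpy as np
import bbbhotspots as b

phantom = b.generate_phantom(
    (48, 48, 48),
    lesion_spec=b.LesionSpec(lacunes=b.LesionClassSpec(3, (2.0, 2.0))),
    seed=1,
)
truth = b.generate_truth_maps(
    phantom,
    focus_spec=(b.FocusSpec(3, attach="lacune_rim"),),
    seed=2,
    texture_log_sd=1.0,
)
vif = b.generate_vif()
dce = b.synthesize_dce(truth, vif, noise_sd=0.005, seed=3)

masks = b.build_analysis_masks(phantom.labels)
maps = b.map_patlak(dce, vif, masks.wm_eroded)
ps = np.where(np.isfinite(maps.ps), maps.ps, 0.0)
hotspots = b.detect_hotspots(ps, maps.fit_mask, phantom.atlas)
table = b.classify_hotspot_set(hotspots, b.LesionSet.from_phantom(phantom))
print(hotspots.count, table.count("at_lacune_edge"), sorted(table.lacunes_with_hotspot))
```

prints

```
24 5 [1, 2, 3]
```

— 24 hotspots were detected in the eroded white matter of this phantom, 5
of them touch a lacune edge, and all three planted lacunes carry at least
one edge hotspot (the three rim foci were planted deliberately, so this is
the expected recovery).

A command-line interface mirrors the library:

```bash
bbbhotspots run-all --outdir demo_run --n-patients 5 --seed 1
```

writes per-patient NIfTI volumes, hotspot/colocalization CSVs, cohort
tables and a hashed run manifest under `demo_run/`.

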