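# corticompare

Head-to-head comparison of surface-based cortical-thickness pipelines on a
common hybrid template.

## The problem

Different cortical-thickness pipelines (a Civet-style "CV" pipeline
and a Freesurfer-style "FS" pipeline) reconstruct the same cortex as
surfaces with different morphology, different tessellation resolution
(ICO6 vs ICO7, i.e. 2·(10·4⁶+2) = 81 924 vs 2·(10·4⁷+2) vertices) and a
systematic thickness offset (the FS-style reading is ~30% / ~1 mm
thinner).  Before the two per-vertex thickness arrays T_CV and T_FS can be
compared, their surfaces must be brought into spatial and topographical
correspondence.  `corticompare` implements the full comparison framework
and exercises it on synthetic two-pipeline cohorts that emulate a
four-group longitudinal Alzheimer's study design (CTR/sMCI/pMCI/AD,
n = 69/37/27/52, at baseline, month 12 and month 24).

## The method

1. **Hybrid template.**  Per-pipeline average surfaces (from 10 CTR +
   10 sMCI + 10 AD subjects) are registered by a free-form deformation:
   the target surface is voxelized into an edge map f = exp(−d/σ), its
   gradient is diffused into a **gradient vector flow** field
   v ← v + dt·[μ∇²v − |∇f|²(v − ∇f)] (the GVF energy
   ∫ μ|∇v|² + |∇f|²|v−∇f|² is checked non-increasing on every run), and
   the field drives a cubic B-spline **FFD** whose control-point
   increments are fitted by least squares under a blended
   (1−p)·membrane + p·thin-plate penalty.
2. **Correspondence.**  **Closest Point Search** assigns every hybrid
   vertex its Euclidean nearest target vertex (exactly equal to brute
   force; ties break to the lowest index), pairing T_CV and T_FS per
   vertex.
3. **Statistics.**  Vertex-wise paired t (within-group thinning) and
   Welch t (between groups) maps with Benjamini–Hochberg FDR (α = 0.01);
   per-vertex disease effect ΔFS − ΔCV (negative ⇒ the FS-style pipeline
   registers more atrophy); overlap maps; ROI-wise one-way ANOVA with
   Tukey–Kramer post-hocs (α = 0.05 cross-sectional / 0.01 longitudinal);
   Hedge's g = J·Δ/s_pooled with J = 1 − 3/(4(n₁+n₂)−9) and cross-pipeline
   z-tests; Pearson correlations vs MMSE and hippocampal volume with
   Steiger's Z for dependent correlations; Kendall τ-b with the Greiner
   conversion r = sin(πτ/2); effect-size-gated (|g| > 0.8 / 0.6)
   sequential-forward-selected logistic ROC with Hanley–McNeil AUC
   standard errors and correlated-AUC comparison.

## Worked example

```python
import dataclasses
import numpy as np
import corticompare as cc

template = cc.build_cortex_template(2, radius=30.0)   # two-hemisphere ICO2
registry = cc.load_roi_registry()                     # the 28-ROI registry
atlas = cc.build_synthetic_atlas(template, registry, seed=1)
cohort = cc.make_cohort(cc.CohortDesign(seed=1))      # 185 subjects

cv = cc.render_pipeline_observation(
    cohort, dataclasses.replace(cc.CIVET_PROFILE, resolution_subdiv=2),
    atlas, template)
fs = cc.render_pipeline_observation(
    cohort, dataclasses.replace(cc.FREESURFER_PROFILE, resolution_subdiv=2),
    atlas, template)
ratio = np.mean([m.values.mean() for m in fs.maps.values()]) / \
        np.mean([m.values.mean() for m in cv.maps.values()])
print(f"whole-cortex FS/CV thickness ratio: {ratio:.3f}")

bsl = cohort.thickness[(cohort.thickness.timepoint == "BSL")
                       & (cohort.thickness.roi_id == 12)]
g = cc.hedges_g_from_samples(bsl[bsl.group == "CTR"]["thickness"],
                             bsl[bsl.group == "AD"]["thickness"])
print(f"CTR-vs-AD Hedge's g in ROI 12: {g.g:.2f} (se {g.se_g:.2f})")
```

prints

```
whole-cortex FS/CV thickness ratio: 0.700
CTR-vs-AD Hedge's g in ROI 12: 1.10 (se 0.20)
```

The 0.700 ratio is the injected 30% between-pipeline offset recovered from
the rendered vertex maps; g ≈ 1.1 in the posterior middle temporal gyrus
(ROI 12) is the strong AD-signature regime (|g| > 0.8) that gates the ROC
feature selection.

The whole cascade — simulate, register, correspond, vertex and ROI
statistics, effect sizes, correlations, ROC — runs as one command:

```sh
corticompare run-all --seed 1 --out study/
```

which writes tidy CSV/JSON outputs, a checksummed run manifest and a
markdown report under `study/`.

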