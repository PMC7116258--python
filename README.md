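# pdbiotype

Neuroanatomic biotype discovery for early Parkinson disease (PD), as a
tested, reusable pipeline.

Patients with newly diagnosed PD are clinically heterogeneous: motor and
non-motor symptoms, and the speed at which they worsen, vary widely between
individuals. One hypothesis is that this heterogeneity reflects distinct
*biotypes* — subgroups defined by shared neuroanatomy rather than by
symptom checklists. This package implements the analysis chain that finds
such biotypes from structural MRI and tests whether they predict disease
progression:

1. **Deformation-based morphometry (DBM).** Given the displacement field
   u(x) of a nonlinear registration to a template, the local volume ratio
   at each voxel is the Jacobian determinant `det(I + ∂u/∂x)`; values > 1
   mean the subject is locally larger than the template. Maps are smoothed
   with a Gaussian kernel specified by its FWHM
   (σ = FWHM / (2√(2 ln 2))), 8 mm by default.
2. **Symptom-correlated voxel selection.** Voxel values are residualized
   against age, sex, education, race and site; a voxel is kept when its
   Spearman rank correlation with any of six baseline clinical scores
   (MDS-UPDRS I, II, III, total, tremor, PIGD) is significant at an
   uncorrected two-sided p < 0.01. The union over scores is the
   neuroanatomic feature set.
3. **Biotyping.** PCA to the smallest component space holding ≥ 90% of
   the variance; Ward hierarchical clustering of the correlation distance
   1 − r between participants' component-score rows; cluster number chosen
   by the Calinski–Harabasz criterion CH = [B/(k−1)]/[W/(n−k)];
   cross-method stability quantified by Cohen's κ against k-means.
4. **Validation.** Voxelwise biotype-vs-control t maps under
   Benjamini–Hochberg FDR control; baseline comparison tables (t / χ²,
   FDR across the family); and a stratified 10-fold cross-validated
   RBF-kernel SVM that diagnoses the biotype of a held-out patient from
   the neuroanatomic features alone.
5. **Progression.** Per outcome, a linear mixed model
   `y = β₀ + β_bio·bio + β_t·t + β_int·(bio×t) + covariates + b₀ᵢ + b₁ᵢ·t + ε`
   with correlated subject random intercepts/slopes, fitted by REML;
   `β_int` is the biotype slope contrast per month, FDR-adjusted across
   outcomes.

Real cohorts of this kind are access-controlled, so the package ships a
seeded synthetic-cohort generator (`pdbiotype.synthetic`) that plants two
biotypes in a "subcortical" block of the voxel grid — one contracted, one
expanded relative to controls — with site/age/sex confounds, score-voxel
correlations by construction, and biotype-specific longitudinal slopes.
Every stage is therefore testable against known ground truth.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from pdbiotype import (SimulationConfig, simulate_cohort, smooth_fwhm,
                       ConfoundModel, select_features, discover_biotypes,
                       report_biotype_shares, crossval_svm)

cfg = SimulationConfig(n_pd=120, n_hc=60, seed=11)
maps, cohort, truth = simulate_cohort(cfg)
X = np.stack([smooth_fwhm(m, 8.0).values.ravel() for m in maps])
is_pd = (cohort["group"] == "PD").to_numpy()
model = ConfoundModel.fit(X[is_pd], cohort[is_pd])
resid = model.residuals(X[is_pd], cohort[is_pd])
fmask = select_features(resid, cohort[is_pd], alpha=0.01)
print("union voxels:", fmask.union_count)
comps, biotypes = discover_biotypes(resid[:, fmask.union], seed=11)
print("components:", comps.n_components, "| k:", biotypes.k,
      "| kappa vs k-means:", round(biotypes.kappa_kmeans, 3))
print(report_biotype_shares(biotypes.labels).to_string(index=False))
print("ARI vs planted truth:", round(adjusted_rand_score(truth.biotype, biotypes.labels), 3))
m = crossval_svm(resid[:, fmask.union], biotypes.labels, folds=10, seed=11)
print(f"SVM accuracy {m.accuracy:.3f}, sensitivity {m.sensitivity:.2f}, "
      f"specificity {m.specificity:.2f}, AUC {m.auc:.3f}")
```

prints

```
union voxels: 1315
components: 86 | k: 2 | kappa vs k-means: 0.982
 biotype  n  percent
       1 44    36.67
       2 76    63.33
ARI vs planted truth: 0.934
SVM accuracy 1.000, sensitivity 1.00, specificity 1.00, AUC 1.000
```

Of the 13,824 voxels on this desk-scale 24³ grid, 1,315 correlate with at
least one baseline score after confound removal; 86
principal components hold 90% of their variance; the Calinski–Harabasz
criterion picks k = 2; the Ward partition splits 36.67% / 63.33% and
agrees almost perfectly with k-means (κ = 0.98) and with the planted
ground truth (ARI = 0.93). Biotype 1 is, by convention, the cluster with
the *lower* mean selected-feature value — the atrophy group. The SVM
re-identifies the biotypes of held-out patients essentially perfectly on
this clean synthetic cohort; on real data the analogous figures are
substantially lower.

The same run from the shell:

```bash
pdbiotype run --seed 11 --out-dir out/        # full pipeline, manifest, CSVs
pdbiotype dbm --field u.nii.gz --out dbm.nii.gz --fwhm 8   # file-level DBM
```

## Layout

| module | contents |
| --- | --- |
| `pdbiotype.synthetic` | seeded cohort/field/longitudinal generators with ground truth |
| `pdbiotype.morphometry` | Jacobian-determinant DBM maps, FWHM smoothing, NIfTI I/O |
| `pdbiotype.feature_selection` | confound residualization, Spearman voxel selection |
| `pdbiotype.biotyping` | PCA, correlation distance, Ward, CH selection, k-means, κ |
| `pdbiotype.validation` | contrast maps, BH-FDR, baseline tables, CV-SVM diagnosis |
| `pdbiotype.progression` | random-slope mixed models, progression summary |
| `pdbiotype.pipeline` / `cli` | orchestration, manifests, `pdbiotype` command |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
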