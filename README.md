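# aphasiamap

Unified behavioural–computational–neural analysis of word-production errors
in post-stroke aphasia.

People with aphasia (PWA) make characteristic errors when naming pictures —
semantic substitutions ("dog" for *cat*), formal errors ("mat"), mixed
errors ("rat"), unrelated words, non-words, and omissions.  The interactive
two-step model of word production explains these profiles with just two
patient-specific parameters: the lexical–semantic connection weight *s* and
the lexical–phonological weight *p*, both constrained below a "normal"
level; lower weights model greater impairment.  This package re-implements,
as one tested pipeline, the combined analysis that relates those model
parameters to (i) fine-grained naming-error categories, (ii) orthogonal
behavioural factors extracted from a neuropsychological battery by
cross-validated PCA, and (iii) lesion anatomy via voxel-based correlational
methodology (VBCM) with permutation cluster-level FWE correction.

It is aimed at researchers in aphasiology / computational neuropsychology
who want a reproducible, scriptable version of this analysis chain, and it
ships a synthetic-cohort generator with known ground truth so every stage
can be validated without patient data.

## What it computes

1. **Error coding** (`aphasiamap.errcode`) — classify each naming response
   into the 14-category scheme (plus *correct* and *not-a-incorrect*),
   collapse to the six model categories
   {correct, semantic, formal, mixed, unrelated, non-word}, pool
   omission-type responses and renormalise under the independence account.
2. **Model fitting** (`aphasiamap.spmodel`) — simulate the three-layer
   spreading-activation network (features ↔ words ↔ phonemes, two retrieval
   steps, decay q, noise) and fit (ŝ, p̂) per patient by exhaustive grid
   search minimising a chi-square between observed counts and Monte-Carlo
   predicted probabilities, with common random numbers across the grid.
3. **Factor analyses** (`aphasiamap.factors`) — percent-scaling of a
   21-test battery, 5-fold cross-validated choice of the component count
   (minimum prediction RMSE), varimax/promax-rotated PCA with regression
   factor scores, KMO and Bartlett diagnostics, eigenvalue>1 PCA of error
   types, starred correlation tables, withheld-test validation.
4. **Lesion mapping** (`aphasiamap.vbcm`) — 8-mm FWHM smoothing,
   outlier-based lesion delineation against controls (U-threshold 0.5),
   lesion overlap maps, voxelwise OLS of signal intensity on continuous
   behavioural regressors with age/education/lesion-volume covariates, and
   cluster-level FWE correction by Freedman–Lane permutation of the maximum
   cluster size (voxel p = 0.005, cluster p < 0.05).
5. **Synthetic cohorts** (`aphasiamap.synthcohort`) — naming trials drawn
   from the production model at known (s, p) with an independent omission
   process, a battery with a planted 4-factor structure tied to the true
   weights, and volumes with planted lesion–behaviour coupling.
6. **Orchestration** (`aphasiamap.pipeline`) — one `run_all` that produces
   the correlation tables, loading tables, diagnostics, cluster tables and
   a seed-complete manifest.

## Worked example

```python
from aphasiamap import errcode, spmodel
from aphasiamap.synthcohort import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(seed=7), with_volumes=False)
included, eligible = errcode.screen_patients_and_categories(cohort.profiles)
dell = [errcode.recode_to_dell(p) for p in included]

grid = spmodel.default_grid(15)          # coarse demo grid
cache = spmodel.GridCache.build(s_grid=grid, p_grid=grid, n_sims=1500, seed=42)
fits = spmodel.fit_cohort(dell, cache)
print(fits.head(3).round(4))
```

prints (seed 7, demo grid):

```
             s_hat   p_hat  sqrt_s  sqrt_p    chi2  at_boundary_s  at_boundary_p
patient_id
P001        0.0072  0.0193  0.0848  0.1389  4.4037          False          False
P002        0.0037  0.0052  0.0611  0.0720  0.7767          False          False
P003        0.0072  0.0193  0.0848  0.1389  3.1119          False          False
```

Each row is one patient's fitted semantic and phonological weight (and
their square roots, the scale used in all correlation and PCA analyses) and
the chi-square of the best grid point.  Both weights sit well below the
normal cap of 0.1: P002 is the more impaired patient on both routes, while
P001 and P003 retain relatively better phonological than semantic access.

The full pipeline, including PCA and lesion mapping on generated volumes:

```bash
aphasia-run --seed 5 --out results/demo
```

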