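# Methods

This note documents the models, defaults and numerical choices behind
`aphasiamap`, and what the synthetic-cohort tests do and do not establish.

## Response coding

Naming responses are coded into the fine-grained scheme (semantic,
phonemic, neologism, formal, mixed, unrelated, initial, dysfluency,
perseveration, circumlocution, not-a-correct, visual, omission, other,
morphological, plus *correct* and *not-a-incorrect*).  Automatic
classification uses two predicates:

* **Phonological relatedness** — symbol-level only, over a declared
  phoneme inventory: the response keeps the first or last target phoneme in
  position, keeps at least two other phonemes in position, or contains at
  least 30% of the target's phonemes in any position.  No feature-level
  (place/manner) similarity is used, because the category definitions are
  stated purely in terms of phoneme identity and position.
* **Semantic relatedness** — an external human judgement carried on the
  record (or a lexicon lookup table).  It is never computed from word
  forms.

Trials with no response, or whose first complete response fell outside the
10-second window (represented by a `within_time_limit` flag set upstream;
the package never inspects timestamps), are omissions.  A coder-supplied
category always overrides the automatic rule.

Collapse to the six model categories follows the standard mapping: correct,
dysfluency and not-a-correct count as correct; phonemic and neologism as
non-word; omission, circumlocution, initial, visual, other and
morphological join the omission pool; perseverations are re-coded per trial
by the relation of the repeated response to the *current* target;
not-a-incorrect is excluded entirely.  Under the **independence account**,
omissions are assumed to arise from a process independent of lexical
access, so the six remaining proportions are renormalised to sum to 1
before fitting; the omission mass is carried separately.

Screening: patients attempting fewer than 50% of items are excluded; an
error category is dropped from PCA input only if it holds less than 2% of
the pooled group errors *and* is not one of the six categories the model
fit requires.  The 2% screen is applied to pooled group counts, not per
patient.

## The production model

A three-layer spreading-activation network: semantic feature nodes, word
nodes, and slot-structured phoneme nodes (onset/vowel/coda).  Edges are
bidirectional: feature↔word edges carry weight `s`, word↔phoneme edges
weight `p`.  Activation updates are

    a_j(t+1) = a_j(t)·(1 − q) + Σ_i w_ij·a_i(t) + ε,
    ε ~ Normal(0, σ_intrinsic² + (σ_activation · a_j(t))²)

Naming runs in two retrieval steps: a jolt into the target's semantic
features, `steps_per_stage` updates, selection of the most activated word;
then a large boost to that word, another `steps_per_stage` updates, and
selection of the most activated phoneme per slot.  The assembled string is
classified against the lexicon: a word match yields that word's
neighbourhood role (target → correct, semantic/formal/mixed/unrelated
neighbour → that error), anything else is a non-word.  Exact activation
ties (possible only in noise-free runs) are broken uniformly at random.

Defaults (all overridable via `SPParameters`):

| parameter | default | meaning |
|---|---|---|
| q | 0.6 | decay per update step |
| steps_per_stage | 8 | updates per retrieval step |
| jolt_semantic | 100 | total activation injected into the target's features (10 per feature for a 10-feature word) |
| jolt_lexical | 100 | boost to the selected word |
| σ_intrinsic | 0.01 | additive noise SD |
| σ_activation | 0.16 | activation-proportional noise SD |
| cap | 0.1 | "normal" weight; fitted s, p never exceed it |

The fixture lexicon is the five-word *cat / dog / rat / mat / log*
neighbourhood with 10 features per word.  Related neighbours share exactly
one feature with the target; this sharing level was calibrated so that the
unimpaired network (s = p = cap) names ≈97% of trials correctly, the normal
profile reported for this model family.  With heavier feature sharing the
interactive feedback makes mixed errors implausibly frequent in the intact
network.

Two small departures from textbook intuition are inherent to the
interactive dynamics and are documented by tests rather than patched:

* the expected correct rate is *not* perfectly monotone in `p` at the very
  top of the range — near the cap, stronger word→phoneme→word feedback
  slightly raises lexical competition (a dip of at most ~3 points);
* an all-non-word profile cannot pin `p` below ≈0.005, because noise-driven
  phoneme assembly still produces a real word about 25% of the time, so the
  non-word rate saturates near 0.75 over a flat low-`p` basin.

## Fitting

`fit_parameters` performs an exhaustive search over a 50×50 logarithmically
spaced grid on (10⁻³, cap] per axis, minimising

    χ²(s, p) = Σ_c (O_c − n·π_c(s, p))² / max(n·π_c(s, p), 0.5)

where O are observed six-way counts and π are Monte-Carlo predicted
probabilities (default 10⁴ simulated trials per grid point).  Design
choices:

* **Grid floor 10⁻³** — below it a weight's contribution falls under the
  network's intrinsic noise floor and the response profile saturates, so
  grid mass there is unidentifiable by construction.
* **Common random numbers** — every grid point reuses the same noise
  realisations, so the χ² surface is smooth in (s, p) and the argmin is not
  dominated by simulation noise.  The predicted-probability table is
  patient-independent and cached (`GridCache`, one build per cohort).
* **Expected-count floor 0.5** — guards near-zero predicted cells.
* **Ties** resolve to the least-impaired grid point (largest indices),
  consistent with the cap constraint's logic that weights sit as close to
  normal as the data allow.

Identifiability: from a 124-trial six-way profile the weights are
recoverable only to roughly ±15–20% relative error (≈3–4 steps of the
4.8%-spaced default grid) in the mid range, and `s` is flatter than `p`
because the non-word rate is the single most diagnostic category.  This
floor is set by multinomial observation noise, not by the optimiser:
fitting noise-free probability vectors recovers the generating grid point
to within one step, and chi-square, multinomial likelihood and RMSD
objectives give indistinguishable scatter.

## Factor analyses

All PCA operates on the correlation matrix of z-scored percent scores
(mixed-scale battery).  Component count is chosen by 5-fold CV: loadings
are fitted on training folds; each held-out cell is predicted by
least-squares projection of the row's remaining variables onto the loading
matrix with the target variable's row deleted (single pass, no EM
iteration); the k minimising mean RMSE wins, ties to the smaller k.
Rotations use Kaiser normalisation; promax (power 4) is built on the
varimax solution; factor scores use the regression method, which makes
varimax scores exactly uncorrelated.  Rotated factors are reported in
decreasing order of explained variance with the dominant loading positive,
so output is deterministic.  KMO uses the anti-image partial-correlation
form; Bartlett's χ² = −(n−1−(2v+5)/6)·ln|R| with df = v(v−1)/2.  The
error-type PCA retains components with eigenvalue strictly greater
than 1.  Correlation tables star raw two-sided p values at 0.05/0.01/0.001
(a Holm-corrected variant is available by flag); no correction is applied
by default to mirror standard reporting practice for these tables.

## Lesion mapping

Volumes must already share one grid; no spatial normalisation is performed.
Smoothing is separable Gaussian, per-axis SD = FWHM/(2√(2 ln 2)) converted
to voxels, constant-padded.  Lesion delineation is a transparent surrogate
for fuzzy outlier clustering: per voxel, |z| of the patient against the
control mean/SD is squashed by a logistic with midpoint 3 SD and unit
slope, and the U-threshold 0.5 cut marks voxels beyond ≈3 control SDs;
zero-variance voxels are excluded.  This preserves the published interface
(a [0,1] abnormality map binarised at U = 0.5) without claiming equivalence
to the original clustering algorithm.

VBCM fits voxelwise OLS of intensity on the behavioural regressor(s) plus
intercept, age, education and (by default) lesion volume, in `separate` or
`simultaneous` mode; the positive direction (higher score ↔ more intact
signal) is tested by default.  Cluster inference: supra-threshold voxels at
the one-sided t cutoff for voxel p = 0.005 form 26-connected clusters
(connectivity configurable); the null of the maximum cluster size comes
from Freedman–Lane permutation (data residualised against the nuisance
design, rows permuted, re-residualised, refitted), and corrected
p = (1 + #{null max ≥ size}) / (n_perm + 1).  Significance uses p ≤ α, the
exact-test convention.  The analysis mask is the union of voxels with
nonzero control variance and voxels lesioned in at least one patient.
Coordinates are 0-based voxel indices with mm offsets from the volume
origin; no atlas space is claimed.

## Synthetic cohorts

Defaults mirror the reference study conditions: 53 patients, 19 controls,
124 naming items, a 21-measure battery in four planted families
(phonology 6, semantics 5, auditory working memory 5, executive 5; primary
loading 0.8, noise SD 0.4), and 40×48×40 volumes at 4 mm — a desk-scale
stand-in for a 1 mm MNI grid that preserves the analysis structure at ~1%
of the memory.

* True weights are sampled uniformly over the interior 80% of the fitting
  grid, avoiding boundary pile-up in recovery tests.
* Omissions overlay naming trials independently with probability
  logistic(−4.2 − 1.3·log₁₀ s), i.e. ≈10% at s = 0.03 rising to ≈35% at
  s = 0.002 — an impairment-linked rate range typical of naming studies —
  so the independence account holds by construction and omissions carry a
  planted negative association with s.
* Latent abilities are unit-variance Gaussians linked to the weights:
  phonology = 0.9·z(√p), semantics = 0.75·z(√s), working memory =
  0.45·z(√s) (plus independent noise), executive independent — reproducing
  the qualitative pattern that √p aligns with phonology only while √s
  spreads over semantics and working memory.
* Volumes: an ellipsoidal "brain" template (intensity 100) plus Gaussian
  noise (SD 2); patients additionally lose up to 35 intensity units inside
  three planted spherical regions whose severity is the cohort-rank
  deficit of the mapped variable (√s region, √p region, working-memory
  region); age (−0.15 intensity/year) and education (+0.2/year) inject
  genuine nuisance structure.

What the synthetic cohort does **not** emulate: realistic vascular lesion
geometry, registration error, scanner artefacts, non-Gaussian score
distributions, missing data, or aphasia subtypes.  Green tests therefore
establish that the pipeline recovers what it is supposed to recover under
its own model assumptions — not that those assumptions hold in any real
cohort.

## Problem sizes used in tests

The test suite and the acceptance script run at the study conditions where
feasible on one CPU: the full 50×50 grid cache at 10⁴ simulations per
point, 53-patient cohorts, 25-replicate selection/rotation sweeps,
199-permutation cluster tests, and a 100–200-replicate familywise
calibration.  Coarser grids (12–15 points) and smaller cohorts appear only
in unit tests of mechanics, never in acceptance measurements.

## Known limitations

* The fitter documents equivalence to its own stated procedure, not bit-level
  equivalence to the original online fitting service, whose objective and
  grid are unpublished.
* Weight recovery from 124 trials is limited to ≈±15–20% relative error by
  observation noise (see *Fitting*); studies needing finer resolution need
  more naming trials, not a finer grid.
* The lesion detector is a calibrated surrogate, not the published fuzzy
  clustering method.
* Permutation cluster correction replaces random-field theory; cluster
  p values are exact under exchangeability but not comparable to RFT
  p values voxel for voxel.
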