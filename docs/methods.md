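# Methods

This note documents the models, conventions and design choices behind
`deltarad`, in the spirit of a statistical package's methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The analysis being modelled

The pipeline reproduces the structure of a nested case–control delta-
radiomics study in a CT lung-screening population: nodules are imaged at a
baseline screen (T0) and a follow-up screen roughly a year later (T1);
quantitative features are extracted at both timepoints; per-feature changes
Δ = T1 − T0 ("delta features") are formed without time normalisation, since
the inter-screen interval is nearly constant across subjects (median ≈ 375
days in the screening setting this emulates, so a per-subject time covariate
would add nothing); and case–control classifiers are trained per nodule
size class and evaluated on a held-out test cohort.

Cohort structure: a training cohort of 83 cases / 172 controls and a test
cohort of 77 cases / 135 controls, the controls frequency-matched 2:1 —
matching removes demographic confounders by design, which is why the
simulator generates no demographic covariates at all. Size classes by
baseline longest diameter: small < 6 mm, intermediate 6–16 mm, large
≥ 16 mm, with lower bounds inclusive ([6, 16) vs [16, ∞)); a two-class
variant merges everything ≥ 6 mm because the large class is very thin
(16 cases / 7 controls in the default training mix).

## Synthetic cohorts

Two generators share `CohortDesignParams`.

**Feature-table mode** (fast path, used by all statistical-stage tests):
each subject carries standardised latent traits; *informative baseline*
features shift case means by `effect_size` SD at both timepoints,
*informative delta* features shift only the case T1 values (default the
same size, separately settable via `delta_effect_size`), and independent
measurement noise is added at each timepoint with SD chosen as
σ_n = sqrt(1/ccc − 1) so that a stable feature's T0/T1 concordance over
controls is approximately `retest_ccc_target`. Subjects are allocated to
size classes by largest-remainder rounding of the per-arm mixes, so stratum
counts are exact and reproducible (the default mixes reproduce the
14/53/16 case and 40/125/7 control training strata, hence the 125 − 53 = 72
SMOTE synthetics in the intermediate stratum at a 1:1 target).

**Image mode**: each subject gets a nodule phantom — an ellipsoid of the
drawn diameter (uniform within its size-class range), in-plane eccentricity
U(0, 0.6), 0–3 cone-shaped spiculations of length 0.3 × radius biased
toward the axial plane, spatially correlated Gaussian HU texture (mean
N(−40, 20) HU, SD U(40, 100) HU, correlation length 1.5 mm), in −800 ± 50 HU
lung parenchyma at 0.7 mm isotropic voxels, 20% attached to a +40 HU planar
pleural wall (the nodule is flattened one-tenth of a radius against the wall
so the contact is a face rather than a single tangent voxel — this gives the
border-composition features real dynamic range). Between screens, case
nodules are rescaled isotropically by `case_growth_factor` (default 1.26,
one volume doubling over the year — a typical malignant doubling time) and
gain `case_texture_shift` = 15 HU of texture SD; controls keep their shape
exactly (factor 1.0) up to a 2% re-scan diameter jitter. The geometry RNG is
separated from the texture RNG so the follow-up scan rescales the *same*
shape while regenerating texture — with zero jitter a control's mask is
bit-identical across screens.

What the generators deliberately do **not** emulate: scanner/reconstruction
effects, DICOM semantics, segmentation error, demographic covariates,
multiple nodules per subject, and any real-data feature correlation
structure. Passing tests therefore demonstrate the *machinery* (and the
qualitative delta-signal recovery), not clinical performance; the headline
AUROCs of the motivating study live on trial data this package does not
touch.

## Feature definitions and conventions

The engine implements the ~22 features the final models consume, not a full
219-feature vendor set. Conventions: 6-connectivity in 3D, 4-connectivity
in 2D; voxel centres, distances in mm via the spacing; population (1/n)
moments for intensity SD; the *representative slice* is the axial slice of
maximal mask area, ties to the lowest index; 2D features are computed there.

Several names have no recoverable published formula; the operationalisations
chosen here are:

- **Circularity** 4πA/P², with both perimeter and area taken from the same
  marching-squares contour of the lightly smoothed (σ = 1 px) slice mask, so
  the isoperimetric bound guarantees values ≤ 1 and a digital disk scores
  ≈ 0.99 rather than the staircase-biased ≈ 0.84.
- **Roundness** 4A/(πLD²) with A the pixel area and LD the boundary-centre
  longest diameter *extended by one pixel*: pixel area includes the
  half-pixel rim beyond boundary centres, so the comparison diameter must
  too, keeping a disk ≤ 1.
- **Asymmetry** 1 − minor/major axis of the best-fit ellipse from the
  slice's second moments (plus the s²/12 pixel self-moment, which keeps
  single-pixel masks finite); a 2:1 ellipse scores ≈ 0.5.
- **MacSpic** counts 4-connected residue components (≥ 4 px, smaller pieces
  are digitisation slivers) left by a morphological opening with a disk of
  radius LD/8 — an opening-residue protrusion counter.
- **avgRLN** quantises in-mask HU uniformly into 16 grey levels (exposed as
  a parameter) and averages run-length nonuniformity Σ_j(Σ_i p(i,j))²/Σp
  over the 13 unique 3D directions; out-of-mask voxels break runs. The
  implementation gathers whole lines per direction and run-length-encodes
  them vectorised; a brute-force run enumerator validates it in the tests.
- **Laws energies** are mean |response| of the separable kernel over
  in-mask voxels divided by the same statistic for the all-level L5 kernel
  (removing the HU scale); the non-"3D" variants apply the first two tokens
  per axial slice and average over mask slices, ignoring the third token
  with a logged notice — consistent with a slice-based segmentation
  heritage. A mask thinner than the 5³ support falls back to the planar
  value for the 3D feature.

## Stability filter

Lin's CCC with population moments; dynamic range
DR = 1 − mean|x−y|/(max(x∪y) − min(x∪y)), the mean-absolute-difference-over-
pooled-range form of the reproducibility index (the quantity is named but
not printed in the motivating work; this is the standard test/retest
construction). A feature is *stable* iff both exceed the threshold
(default 0.95, strict). Degenerate cases: equal constant sequences are
perfectly concordant (returned as 1 with a warning); zero pooled range means
a constant, perfectly repeatable feature (DR 1 with a warning).

The filter runs on the training cohort only (never the test cohort). Whether
to include cases is genuinely open: cases *really change* between screens,
so the all-train-subjects variant (default, matching the original C1-style
construction) tends to reject exactly the features whose deltas carry
signal. `stability_on: train_controls` restricts the filter to controls,
measuring pure test/retest noise; the packaged demo uses it for that reason.

## Selection, SMOTE, classifiers

**ReliefF**: all instances in index order (no subsampling), 10 nearest hits
and misses by Euclidean distance on min–max scaled features, ties broken by
index — fully deterministic; constant features score exactly 0. **CFS**:
merit k·r̄_cf / sqrt(k + k(k−1)·r̄_ff) on absolute Pearson correlations
(zero-variance features contribute 0), searched by greedy forward best-first
with a 5-expansion stall limit, result ranked by admission order; if the
search returns fewer than k features the model uses the smaller set.

**SMOTE**: minority examples interpolated toward one of their k = 5 nearest
minority neighbours (distances on min–max scaled features; scaling affects
the distance only). The interpolation point is drawn independently **per
feature** — the literal reading of the procedure description this follows —
rather than once per instance as in canonical SMOTE; `per_feature_u=False`
restores the canonical variant. Default target is 1:1 balance (the amount
was unstated). Synthetic rows therefore live in the per-feature interval of
their seed pair. SMOTE is applied to the training split only, after feature
selection by default (the original ordering is unstated; both orders are
runnable by composing the library functions).

**Classifiers** are scikit-learn components behind a fit/predict-proba
contract: decision tree, Gaussian naive Bayes, random forest (100 trees,
seeded), and SVMs with RBF/linear kernels whose C ∈ {2⁻⁵…2¹⁵} and
γ ∈ {2⁻¹⁵…2³} (steps of 4×) are chosen by 5-fold grid search on the training
set maximising AUROC (folds shrink if a class is tiny; libsvm iterations are
capped at 20 000 to bound worst-case convergence at large C). SVM scores are
a logistic link on the decision function — deterministic and cheap, unlike
Platt calibration's internal CV; only score *ranking* and the 0.5 threshold
are consumed downstream. The rule-based learner is a pruned decision-list
stand-in (depth-3 entropy tree) since no RIPPER implementation is available;
it is logged as such.

## Evaluation and pooling

Case = positive class; hard labels at probability 0.5 (threshold unstated in
the original, 0.5 is the neutral choice). AUROC is the normalised
Mann–Whitney U with midranks (exactly the all-pairs concordance with ties
worth ½ — asserted against a brute-force oracle). CIs: Hanley–McNeil
analytic SE for AUROC (a 2000-resample bootstrap is available), normal
approximation p ± 1.96√(p(1−p)/n) for proportions, clipped to [0, 1].
Pooling across strata sums confusion matrices (micro-averaging) and
concatenates probability lists for the overall AUROC; because strata may
score on different scales, a pooled AUROC can be lower than every
per-stratum AUROC — this is a property of the pooling semantics, preserved
deliberately.

The model search selects the best spec per (feature kind × size class) by
**test-cohort** AUROC, mirroring the original best-on-test protocol. That
protocol optimistically biases the winners' estimates; every report and
results file carries this caveat, and the full leaderboard is emitted for
audit. Ties break toward fewer features, then classifier enumeration order.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical config + seed reproduces results
byte-for-byte. The test suite exercises the full-size 255/212-subject
design for the statistical stages and the delta-improvement property at
20 seeds on the intermediate stratum with the four fast classifiers and
SMOTE on (the SVM grid search is covered by its own tests; including it in
the repeated-seed study adds cost without changing the question). The
packaged demo runs 200 subjects with the same reduced classifier grid.
`scripts/acceptance.py` uses the full-size design for one seed.

## Known limitations

- Feature formulas for the vendor-defined names are reconstructions;
  absolute values are not comparable to the original software's output,
  only the analysis structure is.
- The phantom texture model (smoothed Gaussian field) has no anatomical
  content; Laws/RLN features discriminate texture *changes*, not pathology.
- The rule-list classifier is contract-level, not a RIPPER reimplementation.
- Proportion CIs use the normal approximation to mirror the symmetric
  intervals of the original tables; exact intervals would differ near 0/1.
- With `stability_on: train` (the default), strongly delta-informative
  features can be filtered out before modelling — an inherent tension of
  using two real screens as a test/retest pair, not a bug.
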