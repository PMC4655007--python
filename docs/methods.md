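# Methods

## Model and procedure

`bootsvm` estimates the generalisation accuracy of an RBF-kernel
soft-margin SVM classifier on a small labelled sample × variable matrix,
and tests that estimate against chance. The unit of computation is one
*member*: a stratified holdout split, hyperparameter tuning on the
training portion only, a final refit, and a score on the held-out
portion. An ensemble is N members with independent splits; the reported
accuracy is the mean of member holdout accuracies, so its sampling
variability over splits is averaged out rather than hidden. Fused
majority voting over members is used only to classify *new* samples
(members have different test sets, so a fused accuracy on the training
study would mix train and test rows).

Assumptions: samples are exchangeable within class (splits are drawn
uniformly within class); variables are numeric, complete, and already
aligned/preprocessed; classes each contribute at least two samples.
Missing values are rejected, never imputed — imputation is an upstream
modelling decision this package refuses to make silently.

## The bootstrap objective

For a training set of size n, B bootstrap draws of size n (with
replacement) are frozen once per member. A draw leaves on average
(1 − 1/n)ⁿ → 1/e ≈ 37 % of samples out of bag; those form the internal
test set. The tuning objective is the mean over the B frozen splits of
the misclassification fraction of an SVM fitted on the in-bag rows at
the candidate (log₂C, log₂γ). Freezing the splits makes the surface
deterministic, so the optimiser's comparisons are meaningful and two
evaluations of the same point agree exactly. Degenerate draws — empty
OOB set, or an in-bag multiset covering fewer than two classes (both
possible at very small n) — are redrawn, up to 100 attempts.

## The constrained simplex (Box complex) search

Hyperparameters live in the closed box log₂C ∈ [−5, 15],
log₂γ ∈ [−15, 5]; the search works in log₂ space because the response
surface is roughly scale-invariant in (C, γ) and the conventional grid
is dyadic. The complex holds k = 4 vertices (twice the dimension, Box's
recommendation), initialised uniformly in the box. Each iteration
reflects the worst vertex through the centroid of the rest with
over-reflection coefficient α = 1.3. Numerical details that matter:

* **Bound retraction.** A reflected point leaving the box has each
  violating coordinate moved to halfway between the violated bound and
  the centroid (never onto the bound itself). Pinning points exactly on
  a face collapses the complex's extent perpendicular to that face and
  stalls the search at boundary non-optima; the halfway retraction
  preserves enough diversity for reflections to pull vertices back
  inside when the optimum is interior.
* **Failed reflections.** A candidate still worse than the worst vertex
  is pulled halfway toward the centroid, up to 20 times, stopping early
  if its value stops changing (OOB-error surfaces are piecewise
  constant, so repeated halvings on a plateau are wasted evaluations).
  If the whole sequence fails to improve on the worst vertex, the
  complex contracts toward its best vertex. The contraction shrinks the
  value spread geometrically, which guarantees the spread-tolerance
  test terminates the run — without it, plateau cycling can burn
  thousands of evaluations.
* **Termination.** Value spread < 10⁻³ or 100 iterations.
* **Restarts.** 3 runs: all but the last start from fresh uniform
  complexes (diversification against a poor initial complex); the last
  is a small complex (5 % of the box span) around the best point found,
  which polishes cheaply instead of re-converging from scratch. The
  best point *ever evaluated* — including rejected candidates — is
  returned.

On smooth test functions the search lands within ~0.05 log₂ units of
the true argmin in under 300 evaluations; on frozen bootstrap
objectives it typically spends 30–60 evaluations, versus 121 for the
coarse grid pass alone, while matching the grid's best value. The
two-stage grid baseline (11 × 11 coarse at step 2², then step 2^0.25
within ±2 log₂ units of the winner, ties toward smaller log₂C then
smaller log₂γ) is included so the efficiency comparison is measurable
in-package.

## The SVM engine

The quadratic program is solved by libsvm through scikit-learn's
bundled Cython bindings. The estimator-level API is bypassed because
the pipeline fits thousands of SVMs on matrices with a dozen rows,
where per-call validation costs ~50× the solve; the test suite pins the
engine to the public `SVC` estimator by asserting exact prediction
agreement on fuzzed problems, and to an independent SLSQP solution of
the SVM dual on a small reference problem. Variables are standardised
(mean/SD learned on the fit rows only; constant variables pass through
with spread 1), and multiclass problems use one-vs-one voting —
the libsvm convention.

## Seeding and parallelism

Every member's seed derives from the master seed by a counter-based
spawn (`SeedSequence(master, spawn_key=(stream, index))`), so results
are bit-identical whether members are built sequentially or on any
number of joblib workers, and permutation replicates are independent of
scheduling. Derived seeds stay below 2³¹.

## Permutation testing

Each permutation shuffles the label vector once (class counts
preserved), rebuilds a complete ensemble with exactly the observed
ensemble's configuration, and records its average test accuracy. The
p-value uses the add-one estimator (1 + #{null ≥ observed})/(1 + P):
it can never be zero, and ties count toward the null. Null quantiles
(five-number summary, upper 95 %/99 %) use linear-interpolation
(type-7) empirical quantiles for cross-language reproducibility. At the
conventional defaults — 100 permutations × 100 members × 100
bootstraps — the scheduled workload is 10⁶ classifier-level bootstrap
iterations; the driver counts them explicitly.

## Synthetic data generator

The generator emulates the statistical shape of binned NMR matrices:
non-negative intensities (baseline lifted 6 noise SDs above the largest
class shift), locally correlated bins (block-diagonal equicorrelation,
blocks of 5 bins, within-block r = 0.6 — neighbouring spectral bins
rise and fall together), and class signal confined to a subset of
informative bins, expressed as a mean shift of `effect_size`
within-class SDs on a per-class contiguous segment. Two deterministic
fixtures mirror common benchmark shapes: 18 × 189 with two balanced
classes at effect size 3 (strong but imperfect separation at n = 12
training samples), and 33 × 164 with four classes (9/8/8/8 — the
four-class total is fixed but its composition is a package convention)
where class 4's shift pattern is a 60/40 blend of class 3's and its
own, making classes 3 and 4 genuinely confusable while 1 and 2 stay
easy.

What the generator does **not** emulate: realistic NMR peak shapes,
chemical-shift axes, baseline drift, heteroscedastic noise, batch
effects, or class imbalance beyond what the spec requests. Passing
tests therefore demonstrate the pipeline's statistical machinery —
leakage-free estimation, calibrated nulls, optimiser efficiency — not
performance on any particular real assay.

## Default parameters

| Parameter | Default | Meaning |
|---|---|---|
| `test_fraction` | 1/3 | Holdout share per member, stratified; per-class test count = round(count × fraction) clamped to [1, count−1] (half-up rounding) |
| `n_members` | 100 | Ensemble size; the accuracy-vs-size curve shows the estimate stabilising well before this |
| `n_boot` | 100 | Frozen bootstrap splits behind each member's objective |
| `n_perm` | 100 | Permutations; with the add-one p-value the smallest attainable p is 1/101 < 0.01 |
| `k` / `alpha` | 4 / 1.3 | Complex size and over-reflection coefficient |
| `tol` / `max_iter` | 10⁻³ / 100 | Simplex termination |
| `restarts` | 3 | Uniform restarts + final polish |
| bounds | log₂C ∈ [−5, 15], log₂γ ∈ [−15, 5] | The conventional search box |

## Problem sizes in the test and acceptance runs

The automated checks scale the defaults down so the full pipeline runs
in minutes on one core: 30-member ensembles with 30 bootstraps for the
fixture builds, 19 permutations of 8-member × 10-bootstrap ensembles
for significance and calibration checks (with `restarts=1` for these
tiny ensembles — observed and null pipelines always share one
configuration, so calibration is unaffected), and 20-sample-per-class
datasets with 50 variables for the optimiser-vs-grid comparisons. The
statistical structure (stratification, freezing, seed derivation) is
identical at every scale.

## Known limitations

* Only the RBF kernel is implemented; the engine's contract
  deliberately excludes polynomial/sigmoid kernels, probability
  calibration, and class weighting.
* The headline metric averages over holdout splits of one dataset; it
  cannot correct for a study population that under-represents real
  variance.
* The Box complex is a local heuristic; restarts mitigate but do not
  eliminate the chance of missing a narrow global optimum on a rugged
  OOB surface (the grid baseline bounds the loss at ≤ 0.02 mean OOB
  error in the packaged checks).
* Ensemble archives embed pickled solver state and are therefore
  Python-version-bound; the JSON manifest (config, seeds, metrics) is
  the portable part.
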