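# bootsvm

Robust RBF-SVM voting ensembles — with bootstrapped hyperparameter tuning
and permutation testing — for classifying biological samples from
multivariate profiles (binned NMR spectra, metabolite tables, any numeric
sample × variable matrix).

## The problem

A single train/test split of a small omics study gives a classification
accuracy that is largely luck: which samples landed in the test set can
swing the estimate by tens of points. Cross-validation is known to be
optimistic on such data. `bootsvm` instead builds **many** independent
classifiers, each on its own stratified holdout split, and reports the
distribution of their honest test accuracies — then asks, via label
permutation, whether that performance could have arisen by chance.

## The method

Each ensemble member is produced by the full pipeline:

1. **Stratified holdout** — a third of the samples (class proportions
   preserved) are set aside and never touched during training.
2. **Bootstrap objective** — B bootstrap samples (drawn with replacement,
   size = |D_train|) are frozen; for hyperparameters (C, γ) the objective
   is the mean misclassification rate of an RBF SVM trained on each
   in-bag set and tested on its out-of-bag complement:

   err(C, γ) = (1/B) Σ_b OOB-error_b(C, γ)

3. **Box-complex search** — a bound-constrained nonlinear simplex
   minimises err over the box log₂C ∈ [−5, 15], log₂γ ∈ [−15, 5]. It
   reflects the worst vertex through the centroid (over-reflection
   α = 1.3), retracts bound violations, and contracts as it nears a
   minimum. It typically needs ~30–60 objective evaluations versus the
   121 of a conventional coarse grid (a two-stage grid search is included
   as the baseline).
4. **Refit and score** — the optimum (C, γ) refits an SVM on all of
   D_train (variables standardised on training statistics only); accuracy
   (%CC = N_c/(N_c+N_nc) × 100) is measured on the untouched test set.

Repeating this N times (default 100) and fusing members by unweighted
majority vote gives the ensemble; its headline metric is the **mean of
member test accuracies**, and per-sample vote fractions quantify
prediction confidence. `permutation_test` rebuilds entire ensembles on
label-shuffled data to form a null accuracy distribution, reported with
a five-number summary, upper 95 %/99 % quantiles, and an add-one
empirical p-value, p = (1 + #{null ≥ observed}) / (1 + P).

## Worked example

Generate a synthetic two-class spectral matrix (18 samples × 189 bins,
the shape of a small urine NMR study), build a 20-member ensemble, test
its significance, and classify samples:

```bash
bootsvm synth --classes 9,9 --variables 189 --informative 20 \
        --effect-size 3 --seed 4 --out urine_like.csv
bootsvm build --data urine_like.csv --labels urine_like_labels.csv \
        --members 20 --boot 20 --seed 7 --out run1
# -> ensemble of 20 members: average test accuracy 93.3%
bootsvm permute --data urine_like.csv --labels urine_like_labels.csv \
        --ensemble run1/ensemble.zip --perms 19 --seed 8 --out perm1
# -> observed 93.3% vs null median 50.0%; p = 0.0500
bootsvm predict --ensemble run1/ensemble.zip --data urine_like.csv \
        --out predictions.csv
```

`run1/metrics.json` then holds

```json
{
 "avg_test_accuracy": 93.33,
 "per_class_accuracy": {"class1": 86.67, "class2": 100.0},
 "mean_objective_evals": 35.45
}
```

meaning: across 20 independent holdout splits the tuned SVMs averaged
93.3 % test accuracy (class1 is the harder class at 86.7 %), and the
simplex needed ~35 objective evaluations per member — well under the
121-evaluation coarse-grid budget. The permutation summary shows the
null distribution centred at 50 % (the chance rate for balanced
two-class data) with upper 95 %/99 % levels of 63.2 %/68.7 %, far below
the observed 93.3 %; p = 0.05 is the smallest value attainable with 19
permutations. `predictions.csv` adds a per-sample vote fraction — e.g.
a sample with 19/20 member votes is called with fraction 0.95.

The same workflow is available as library functions
(`build_ensemble`, `ensemble_predict`, `permutation_test`, …).

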