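"""Ensemble construction, majority-vote fusion and accuracy metrics.

One ensemble member is built by the full pipeline: stratified holdout ->
frozen bootstrap objective on the training rows -> simplex hyperparameter
optimisation -> final refit on the whole training set at the optimum ->
accuracy on the untouched holdout test set. Repeating this N times with
independent splits and fusing the members by unweighted majority vote
gives a classifier whose headline metric — the mean of member holdout
accuracies — is far less at the mercy of one lucky or unlucky split than
any single train/test experiment.

Per-member seeds are derived from the master seed by a counter-based
spawn, so results are bit-identical whether members are built
sequentially or on any number of joblib workers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed
from sklearn.metrics import confusion_matrix

from .data_model import HoldoutSplit, LabeledDataset, stratified_holdout
from .optimizer import OptimizerSettings, box_complex_minimize, make_objective, two_stage_grid_search
from .svm_engine import DEFAULT_BOUNDS, FittedSVM, HyperParamBounds, HyperParams, fit_rbf_svm, predict_svm

__all__ = [
    "TrainedClassifier",
    "Ensemble",
    "PredictionResult",
    "percent_cc",
    "per_class_cc",
    "build_classifier",
    "build_ensemble",
    "ensemble_predict",
    "accuracy_vs_size",
]


def percent_cc(true: np.ndarray, predicted: np.ndarray) -> float:
    """Percentage of correctly classified samples.

    %CC = N_c / (N_c + N_nc) * 100, where N_c and N_nc count correct and
    incorrect classifications.
    """
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    if true.size == 0:
        raise ValueError("cannot score empty label vectors")
    if true.shape != predicted.shape:
        raise ValueError(
            f"length mismatch: {true.shape} true vs {predicted.shape} predicted"
        )
    return float(100.0 * np.mean(true == predicted))


def per_class_cc(
    true: np.ndarray, predicted: np.ndarray
) -> tuple[dict, np.ndarray]:
    """Per-class accuracies and the confusion matrix.

    Per-class accuracy is the row-normalised diagonal of the confusion
    matrix, in percent. Classes absent from ``true`` are omitted. The
    returned matrix has rows = true classes, columns = the union of
    observed label values in sorted order.
    """
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    if true.size == 0:
        raise ValueError("cannot score empty label vectors")
    if true.shape != predicted.shape:
        raise ValueError("length mismatch between true and predicted labels")
    classes = np.unique(np.concatenate([true, predicted]))
    cm = confusion_matrix(true, predicted, labels=classes)
    present = np.isin(classes, np.unique(true))
    accs = {}
    for i, cls in enumerate(classes):
        if present[i]:
            accs[cls.item() if hasattr(cls, "item") else cls] = float(
                100.0 * cm[i, i] / cm[i].sum()
            )
    return accs, cm


@dataclass
class TrainedClassifier:
    """One optimised SVM with its holdout split and test metrics."""

    model: FittedSVM
    split: HoldoutSplit
    opt_params: HyperParams
    opt_value: float
    eval_count: int
    test_accuracy: float
    per_class_test_accuracy: dict
    seed: int


@dataclass
class Ensemble:
    """N independently trained classifiers fused by majority vote."""

    members: list
    avg_test_accuracy: float
    per_class_accuracy: dict
    accuracy_vs_size: np.ndarray
    fused_vote_rule: str
    config_snapshot: dict
    master_seed: int

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(np.concatenate([m.model.classes for m in self.members]))


@dataclass
class PredictionResult:
    """Fused predictions: winning labels, vote fractions, full vote counts."""

    labels: np.ndarray
    vote_fraction: np.ndarray
    vote_matrix: np.ndarray  # (n_samples, n_classes), class order = sorted
    classes: np.ndarray


def _member_seed(master_seed: int, index: int, stream: int = 0) -> int:
    """Counter-based child seed: independent of scheduling order."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(stream, index))
    return int(ss.generate_state(1)[0] % (2**31))


def build_classifier(
    data: LabeledDataset,
    seed: int,
    test_fraction: float = 1.0 / 3.0,
    settings: OptimizerSettings | None = None,
    bounds: HyperParamBounds = DEFAULT_BOUNDS,
    optimizer: str = "simplex",
    scale: bool = True,
) -> TrainedClassifier:
    """Run the full single-classifier pipeline once.

    Holdout -> frozen B-split bootstrap objective on the training rows ->
    hyperparameter optimisation (simplex by default, two-stage grid as the
    baseline) -> refit on all training rows at the optimum -> score on the
    held-out test rows.
    """
    settings = settings or OptimizerSettings()
    rng = np.random.default_rng(seed)
    split = stratified_holdout(data, test_fraction, rng)
    objective = make_objective(
        data.matrix, data.labels, split.train_idx, settings.n_boot, rng, scale=scale
    )
    if optimizer == "simplex":
        opt_params, opt_value, _ = box_complex_minimize(
            objective, bounds, rng, settings
        )
    elif optimizer == "grid":
        opt_params, opt_value, _ = two_stage_grid_search(objective, bounds)
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")
    model = fit_rbf_svm(
        data.matrix[split.train_idx],
        data.labels[split.train_idx],
        opt_params,
        scale=scale,
    )
    true = data.labels[split.test_idx]
    pred = predict_svm(model, data.matrix[split.test_idx])
    accs, _ = per_class_cc(true, pred)
    return TrainedClassifier(
        model=model,
        split=split,
        opt_params=opt_params,
        opt_value=opt_value,
        eval_count=objective.eval_count,
        test_accuracy=percent_cc(true, pred),
        per_class_test_accuracy=accs,
        seed=seed,
    )


def build_ensemble(
    data: LabeledDataset,
    n_members: int = 100,
    test_fraction: float = 1.0 / 3.0,
    settings: OptimizerSettings | None = None,
    bounds: HyperParamBounds = DEFAULT_BOUNDS,
    optimizer: str = "simplex",
    scale: bool = True,
    master_seed: int = 0,
    n_workers: int = 1,
) -> Ensemble:
    """Build N independent members and fuse them.

    Members get counter-derived seeds, so the result is identical at any
    worker count. The headline ``avg_test_accuracy`` is the mean of the
    member holdout accuracies; ``accuracy_vs_size[k-1]`` is the mean over
    the first k members (creation order), showing how the estimate
    stabilises as the ensemble grows.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    settings = settings or OptimizerSettings()
    seeds = [_member_seed(master_seed, i) for i in range(n_members)]

    def one(i: int) -> TrainedClassifier:
        try:
            return build_classifier(
                data, seeds[i], test_fraction, settings, bounds, optimizer, scale
            )
        except Exception as exc:  # noqa: BLE001 - annotate with member index
            raise RuntimeError(f"ensemble member {i} failed: {exc}") from exc

    if n_workers == 1:
        members = [one(i) for i in range(n_members)]
    else:
        members = Parallel(n_jobs=n_workers)(
            delayed(one)(i) for i in range(n_members)
        )

    member_acc = np.array([m.test_accuracy for m in members])
    curve = np.cumsum(member_acc) / np.arange(1, n_members + 1)
    classes = np.unique(data.labels)
    per_class = {}
    for cls in classes:
        key = cls.item() if hasattr(cls, "item") else cls
        vals = [
            m.per_class_test_accuracy[key]
            for m in members
            if key in m.per_class_test_accuracy
        ]
        per_class[key] = float(np.mean(vals)) if vals else float("nan")
    return Ensemble(
        members=list(members),
        avg_test_accuracy=float(member_acc.mean()),
        per_class_accuracy=per_class,
        accuracy_vs_size=curve,
        fused_vote_rule="unweighted-majority",
        config_snapshot={
            "n_members": n_members,
            "test_fraction": test_fraction,
            "optimizer": optimizer,
            "scale": scale,
            "settings": settings.__dict__.copy(),
            "bounds": bounds.__dict__.copy(),
        },
        master_seed=master_seed,
    )


def ensemble_predict(ens: Ensemble, X: np.ndarray) -> PredictionResult:
    """Classify new samples by unweighted majority vote over all members.

    The winning vote fraction is a per-sample confidence: the larger the
    share of members agreeing on the reported class, the more trustworthy
    the call. Ties break deterministically toward the first label in
    sorted class order.
    """
    X = np.asarray(X, dtype=float)
    classes = ens.classes
    class_pos = {c: i for i, c in enumerate(classes.tolist())}
    votes = np.zeros((X.shape[0], classes.size), dtype=int)
    for member in ens.members:
        pred = predict_svm(member.model, X)
        for row, label in enumerate(pred.tolist()):
            votes[row, class_pos[label]] += 1
    winner = votes.argmax(axis=1)  # argmax takes the first max: sorted-order tie-break
    labels = classes[winner]
    frac = votes[np.arange(X.shape[0]), winner] / len(ens.members)
    return PredictionResult(
        labels=labels, vote_fraction=frac, vote_matrix=votes, classes=classes
    )


def accuracy_vs_size(ens: Ensemble) -> np.ndarray:
    """Mean member test accuracy of the first k members, for k = 1..N."""
    acc = np.array([m.test_accuracy for m in ens.members])
    return np.cumsum(acc) / np.arange(1, acc.size + 1)
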