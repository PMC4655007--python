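"""Single RBF-kernel SVM: fit at a given (C, gamma), predict labels.

The soft-margin SVM with Gaussian kernel k(x, x') = exp(-gamma * ||x-x'||^2)
is the base classifier of the pipeline. Hyperparameters are carried in
log2 space inside a closed box (log2 C in [-5, 15], log2 gamma in [-15, 5]
by default) because the search and the conventional grid are both dyadic.

Variables are standardised to zero mean / unit spread using statistics
learned on the fit data only, and the stored scaling is re-applied at
prediction time — test information never leaks into the fit. Multiclass
problems are handled by one-vs-one binary decomposition.

The quadratic-programming solver underneath is libsvm, called through
scikit-learn's bundled Cython bindings rather than the ``SVC`` estimator:
the pipeline refits thousands of very small SVMs inside the optimisation
loop, where the estimator's per-call validation overhead dwarfs the
actual solve. The test suite asserts exact prediction agreement with the
public ``SVC`` estimator on fuzzed problems, so the behavioural contract
(soft margin, RBF kernel, one-vs-one voting, determinism) is pinned to
the reference implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import _libsvm as _libsvm

_libsvm.set_verbosity_wrap(0)  # silence the solver's per-fit chatter

__all__ = ["HyperParams", "HyperParamBounds", "FittedSVM", "fit_rbf_svm", "predict_svm"]


@dataclass(frozen=True)
class HyperParamBounds:
    """Closed box constraints on (log2 C, log2 gamma)."""

    log2C_min: float = -5.0
    log2C_max: float = 15.0
    log2gamma_min: float = -15.0
    log2gamma_max: float = 5.0

    def __post_init__(self) -> None:
        if not (self.log2C_min < self.log2C_max
                and self.log2gamma_min < self.log2gamma_max):
            raise ValueError("hyperparameter bounds must be well-ordered")

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.log2C_min, self.log2gamma_min])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.log2C_max, self.log2gamma_max])

    def contains(self, log2C: float, log2gamma: float) -> bool:
        return bool(
            self.log2C_min <= log2C <= self.log2C_max
            and self.log2gamma_min <= log2gamma <= self.log2gamma_max
        )


DEFAULT_BOUNDS = HyperParamBounds()


@dataclass(frozen=True)
class HyperParams:
    """A point (log2 C, log2 gamma) inside the bound box.

    C is the soft-margin cost (larger C penalises training errors harder);
    gamma is the RBF width (larger gamma gives a more wiggly boundary).
    """

    log2C: float
    log2gamma: float
    bounds: HyperParamBounds = field(default=DEFAULT_BOUNDS, compare=False)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.log2C) and np.isfinite(self.log2gamma)):
            raise ValueError("hyperparameters must be finite")
        if not self.bounds.contains(self.log2C, self.log2gamma):
            raise ValueError(
                f"(log2C={self.log2C}, log2gamma={self.log2gamma}) outside "
                f"bounds [{self.bounds.log2C_min}, {self.bounds.log2C_max}] x "
                f"[{self.bounds.log2gamma_min}, {self.bounds.log2gamma_max}]"
            )

    @property
    def C(self) -> float:
        return float(2.0 ** self.log2C)

    @property
    def gamma(self) -> float:
        return float(2.0 ** self.log2gamma)

    def as_array(self) -> np.ndarray:
        return np.array([self.log2C, self.log2gamma])


@dataclass
class FittedSVM:
    """A trained RBF SVM plus the per-variable scaling learned at fit time.

    ``state`` holds the raw libsvm solution (support-vector indices,
    support vectors, per-class support counts, dual coefficients,
    intercepts, probability placeholders); ``classes`` maps the solver's
    integer codes back to the original label values.
    """

    params: HyperParams
    center: np.ndarray
    spread: np.ndarray
    state: tuple
    classes: np.ndarray


def _learn_scaling(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    spread = X.std(axis=0)
    spread = np.where(spread > 0, spread, 1.0)  # constant variables pass through
    return center, spread


def fit_rbf_svm(
    X: np.ndarray,
    y: np.ndarray,
    params: HyperParams,
    scale: bool = True,
) -> FittedSVM:
    """Fit a soft-margin RBF SVM at the given hyperparameters.

    Rows may be duplicated (bootstrap in-bag multisets are the normal
    input). One-vs-one decomposition handles more than two classes.
    ``scale=False`` disables standardisation for data already on a common
    scale.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} rows but {y.shape[0]} labels")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(f"need at least 2 classes to fit, got {classes.tolist()}")
    if scale:
        center, spread = _learn_scaling(X)
    else:
        center = np.zeros(X.shape[1])
        spread = np.ones(X.shape[1])
    Xs = np.ascontiguousarray((X - center) / spread)
    codes = np.searchsorted(classes, y).astype(np.float64)
    state = _libsvm.fit(
        Xs, codes, svm_type=0, kernel="rbf", C=params.C, gamma=params.gamma
    )
    return FittedSVM(
        params=params, center=center, spread=spread, state=state, classes=classes
    )


def predict_svm(model: FittedSVM, X: np.ndarray) -> np.ndarray:
    """Predict one label per row, applying the stored scaling first."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if X.shape[1] != model.center.shape[0]:
        raise ValueError(
            f"X has {X.shape[1]} variables but the model was fitted "
            f"on {model.center.shape[0]}"
        )
    if X.shape[0] == 0:
        return np.empty(0, dtype=model.classes.dtype)
    Xs = np.ascontiguousarray((X - model.center) / model.spread)
    support, sv, n_sv, coef, intercept, prob_a, prob_b = model.state[:7]
    codes = _libsvm.predict(
        Xs, support, sv, n_sv, coef, intercept, prob_a, prob_b,
        svm_type=0, kernel="rbf", gamma=model.params.gamma,
    )
    return model.classes[codes.astype(np.intp)]
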