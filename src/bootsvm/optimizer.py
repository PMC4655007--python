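"""Hyperparameter search over the (log2 C, log2 gamma) box.

Two searchers minimise the same objective — the mean out-of-bag
misclassification fraction over a frozen set of bootstrap splits:

* :func:`box_complex_minimize` — a bound-constrained nonlinear simplex
  (Box's "complex" method). The complex of k points reflects its worst
  vertex through the centroid of the others with over-reflection
  coefficient alpha, retracts bound-violating coordinates to halfway
  between the bound and the centroid, and moves a stubbornly-worst
  reflected point halfway toward the centroid (contracting the whole
  complex toward its best vertex if that fails). It stops on
  value-spread tolerance or an iteration cap. This is the fast path.

* :func:`two_stage_grid_search` — the conventional baseline: an 11 x 11
  coarse grid over C = 2^-5..2^15, gamma = 2^-15..2^5 (step 2^2), whose
  winner seeds a fine grid (step 2^0.25, +/-2 log2 units, clipped to the
  box).

Every objective evaluation is counted, so the efficiency of the simplex
relative to the 121-evaluation coarse-grid budget is a first-class,
measurable output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import BootstrapSplit, bootstrap_split
from .svm_engine import (
    DEFAULT_BOUNDS,
    HyperParamBounds,
    HyperParams,
    fit_rbf_svm,
    predict_svm,
)

__all__ = [
    "OptimizerSettings",
    "BootstrapObjective",
    "ComplexState",
    "make_objective",
    "box_complex_minimize",
    "two_stage_grid_search",
]


@dataclass(frozen=True)
class OptimizerSettings:
    """Tunables of the simplex search and the bootstrap objective.

    k
        Number of complex vertices; 4 = twice the number of search
        dimensions, Box's original recommendation.
    alpha
        Over-reflection coefficient; 1.3 is Box's classic value.
    tol
        Termination tolerance on the spread (max - min) of vertex values.
    max_iter
        Iteration cap per restart.
    restarts
        Complex runs per search: all but the last from fresh uniform
        starts, the last a local polish around the best point so far;
        the best point over all runs wins.
    n_boot
        Number of frozen bootstrap splits B behind the objective.
    """

    k: int = 4
    alpha: float = 1.3
    tol: float = 1e-3
    max_iter: int = 100
    restarts: int = 3
    n_boot: int = 100

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError("complex needs at least 3 vertices")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.n_boot < 1 or self.max_iter < 1 or self.restarts < 1:
            raise ValueError("counts must be >= 1")


class BootstrapObjective:
    """Mean OOB error of an RBF SVM over B frozen bootstrap splits.

    The splits are drawn once at construction, so the optimiser sees a
    deterministic surface: evaluating the same point twice returns the
    identical value. ``eval_count`` increments on every call.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        splits: list[BootstrapSplit],
        scale: bool = True,
    ) -> None:
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.splits = splits
        self.scale = scale
        self.eval_count = 0
        # splits index into the full dataset; remap not needed because
        # X, y here are the full matrices the indices refer to

    @property
    def n_boot(self) -> int:
        return len(self.splits)

    def __call__(self, params: HyperParams) -> float:
        self.eval_count += 1
        errors = np.empty(len(self.splits))
        for b, split in enumerate(self.splits):
            model = fit_rbf_svm(
                self.X[split.in_bag], self.y[split.in_bag], params, scale=self.scale
            )
            pred = predict_svm(model, self.X[split.oob])
            errors[b] = np.mean(pred != self.y[split.oob])
        return float(errors.mean())


def make_objective(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    n_boot: int,
    rng: np.random.Generator | None = None,
    scale: bool = True,
) -> BootstrapObjective:
    """Freeze B bootstrap splits of ``train_idx`` into an objective.

    ``objective(params)`` is the mean over splits of the misclassification
    fraction of an SVM fitted on the in-bag rows and tested on the OOB
    rows. Only training rows ever enter the splits. Draws whose in-bag
    multiset covers fewer than 2 classes (possible at tiny n, and
    untrainable) are redrawn like empty-OOB draws.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(rng)
    y = np.asarray(y)
    splits = []
    for _ in range(n_boot):
        for _attempt in range(100):
            split = bootstrap_split(train_idx, rng)
            if np.unique(y[split.in_bag]).size >= 2:
                break
        else:
            raise ValueError(
                "could not draw a bootstrap sample covering 2 classes"
            )
        splits.append(split)
    return BootstrapObjective(X, y, splits, scale=scale)


@dataclass
class ComplexState:
    """Vertices, values and evaluation history of one simplex run."""

    vertices: np.ndarray  # (k, 2) in (log2C, log2gamma)
    values: np.ndarray  # (k,)
    iteration: int = 0
    history: list = field(default_factory=list)  # [(point, value), ...]

    def record(self, point: np.ndarray, value: float) -> None:
        self.history.append((point.copy(), float(value)))


_EDGE = 1e-6  # retracted points sit at least this far inside the boundary


def _clip_into(point: np.ndarray, bounds: HyperParamBounds) -> np.ndarray:
    return np.clip(point, bounds.lower + _EDGE, bounds.upper - _EDGE)


def _retract(
    point: np.ndarray, centroid: np.ndarray, bounds: HyperParamBounds
) -> np.ndarray:
    """Pull a bound-violating candidate back inside the box.

    A violating coordinate moves to halfway between the violated bound
    and the centroid rather than onto the bound itself: pinning points
    exactly on a face collapses the complex's extent perpendicular to
    that face and stalls the search at boundary non-optima.
    """
    point = point.copy()
    low = point < bounds.lower + _EDGE
    high = point > bounds.upper - _EDGE
    point[low] = (bounds.lower[low] + centroid[low]) / 2.0
    point[high] = (bounds.upper[high] + centroid[high]) / 2.0
    return _clip_into(point, bounds)


def _as_params(point: np.ndarray, bounds: HyperParamBounds) -> HyperParams:
    return HyperParams(float(point[0]), float(point[1]), bounds=bounds)


def _one_complex_run(
    objective,
    bounds: HyperParamBounds,
    rng: np.random.Generator,
    settings: OptimizerSettings,
    center: np.ndarray | None = None,
    radius_fraction: float = 0.05,
) -> ComplexState:
    span = bounds.upper - bounds.lower
    k = settings.k
    if center is None:
        # initial complex: k random feasible points (bound constraints
        # only, so uniform draws are always feasible)
        vertices = bounds.lower + rng.random((k, 2)) * span
    else:
        # polish run: small complex around a previously found optimum
        radius = radius_fraction * span
        vertices = np.clip(
            center + (rng.random((k, 2)) * 2.0 - 1.0) * radius,
            bounds.lower + _EDGE,
            bounds.upper - _EDGE,
        )
        vertices[0] = _clip_into(np.asarray(center, dtype=float), bounds)
    values = np.empty(k)
    state = ComplexState(vertices=vertices, values=values)
    for i in range(k):
        values[i] = objective(_as_params(vertices[i], bounds))
        state.record(vertices[i], values[i])

    for iteration in range(1, settings.max_iter + 1):
        state.iteration = iteration
        if values.max() - values.min() < settings.tol:
            break
        worst = int(values.argmax())
        centroid = vertices[np.arange(k) != worst].mean(axis=0)
        # over-reflect the worst vertex through the centroid, retracting
        # into the box if the reflection leaves it
        candidate = _retract(
            centroid + settings.alpha * (centroid - vertices[worst]), centroid, bounds
        )
        value = objective(_as_params(candidate, bounds))
        state.record(candidate, value)
        halvings = 0
        while value >= values[worst] and halvings < 20:
            # still the worst: pull halfway toward the centroid
            candidate = _clip_into((candidate + centroid) / 2.0, bounds)
            prev = value
            value = objective(_as_params(candidate, bounds))
            state.record(candidate, value)
            halvings += 1
            if value == prev:
                break  # flat plateau: further halvings cannot help
        if value < values[worst]:
            vertices[worst] = candidate
            values[worst] = value
        else:
            # reflection failed outright: contract the whole complex
            # toward the best vertex so the spread shrinks geometrically
            # and the tolerance test terminates the run
            best = int(values.argmin())
            for i in range(k):
                if i == best:
                    continue
                vertices[i] = _clip_into(
                    (vertices[i] + vertices[best]) / 2.0, bounds
                )
                values[i] = objective(_as_params(vertices[i], bounds))
                state.record(vertices[i], values[i])
    return state


def box_complex_minimize(
    objective,
    bounds: HyperParamBounds = DEFAULT_BOUNDS,
    rng: np.random.Generator | None = None,
    settings: OptimizerSettings | None = None,
) -> tuple[HyperParams, float, ComplexState]:
    """Minimise a black-box objective over the hyperparameter box.

    Runs ``settings.restarts`` complexes — all but the last started from
    uniform random points in the box (diversification), the last a small
    complex around the best point found so far (polish) — and returns the
    best point ever evaluated (including rejected candidates), its value,
    and the state of the restart that produced it. Every iterate is kept
    strictly inside the bounds.
    """
    rng = np.random.default_rng(rng)
    settings = settings or OptimizerSettings()
    best_point: np.ndarray | None = None
    best_value = np.inf
    best_state: ComplexState | None = None
    for restart in range(settings.restarts):
        polish = restart == settings.restarts - 1 and restart > 0
        state = _one_complex_run(
            objective, bounds, rng, settings,
            center=best_point if polish else None,
        )
        points = np.array([p for p, _ in state.history])
        vals = np.array([v for _, v in state.history])
        i = int(vals.argmin())
        if vals[i] < best_value:
            best_value = float(vals[i])
            best_point = points[i]
            best_state = state
    assert best_point is not None and best_state is not None
    return _as_params(best_point, bounds), best_value, best_state


def _grid_axis(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(np.floor((hi - lo) / step + 0.5))
    return lo + step * np.arange(n + 1)


def two_stage_grid_search(
    objective,
    bounds: HyperParamBounds = DEFAULT_BOUNDS,
    coarse_step: float = 2.0,
    fine_step: float = 0.25,
    fine_halfwidth: float = 2.0,
) -> tuple[HyperParams, float, int]:
    """Coarse 11 x 11 grid, then a fine grid around the coarse winner.

    Ties break toward smaller log2 C, then smaller log2 gamma (simpler
    models first). Returns the best point, its value and the total number
    of objective evaluations.
    """
    n_evals = 0

    def sweep(c_axis: np.ndarray, g_axis: np.ndarray):
        nonlocal n_evals
        best = (np.inf, np.inf, np.inf)  # (value, log2C, log2gamma)
        for c in c_axis:
            for g in g_axis:
                v = objective(_as_params(np.array([c, g]), bounds))
                n_evals += 1
                if (v, c, g) < best:
                    best = (v, c, g)
        return best

    coarse_c = _grid_axis(bounds.log2C_min, bounds.log2C_max, coarse_step)
    coarse_g = _grid_axis(bounds.log2gamma_min, bounds.log2gamma_max, coarse_step)
    v0, c0, g0 = sweep(coarse_c, coarse_g)

    fine_c = np.clip(
        c0 + _grid_axis(-fine_halfwidth, fine_halfwidth, fine_step),
        bounds.log2C_min,
        bounds.log2C_max,
    )
    fine_g = np.clip(
        g0 + _grid_axis(-fine_halfwidth, fine_halfwidth, fine_step),
        bounds.log2gamma_min,
        bounds.log2gamma_max,
    )
    v1, c1, g1 = sweep(np.unique(fine_c), np.unique(fine_g))

    value, c, g = min((v0, c0, g0), (v1, c1, g1))
    return _as_params(np.array([c, g]), bounds), float(value), n_evals
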