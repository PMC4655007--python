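"""Permutation testing of ensemble accuracy.

The null hypothesis is that there is no relationship between the data
matrix and the class labels. Each permutation shuffles the label vector
once (class counts preserved), rebuilds a complete ensemble with exactly
the observed ensemble's configuration, and records its average test
accuracy. The collection of null accuracies yields an empirical p-value,
a five-number summary, and one-sided upper 95%/99% quantiles against
which the observed accuracy is judged.

At the conventional defaults — 100 permutations of 100-member ensembles,
each member tuned over 100 bootstrap splits — the scheduled work is one
million classifier-level bootstrap iterations; the instrumented counter
in :class:`PermutationResult` makes that accounting explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import LabeledDataset, permute_labels
from .ensemble import Ensemble, build_ensemble

__all__ = [
    "PermutationResult",
    "permutation_test",
    "empirical_p_value",
    "null_summary",
]


def empirical_p_value(observed: float, null: np.ndarray) -> float:
    """Add-one empirical p-value: (1 + #{null >= observed}) / (1 + P).

    Ties count toward the null, and the estimate is never exactly zero —
    with 100 permutations the smallest attainable value is 1/101.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    return float((1 + np.count_nonzero(null >= observed)) / (1 + null.size))


def null_summary(null: np.ndarray) -> dict:
    """Five-number summary plus upper 95%/99% quantiles of the null.

    Quantiles use linear interpolation (type 7), the cross-language
    default, so summaries reproduce across toolchains.
    """
    null = np.asarray(null, dtype=float)
    if null.size < 2:
        raise ValueError("need at least 2 null values to summarise")
    q = np.percentile(null, [0, 25, 50, 75, 100])
    return {
        "min": float(q[0]),
        "q1": float(q[1]),
        "median": float(q[2]),
        "q3": float(q[3]),
        "max": float(q[4]),
        "upper_95": float(np.percentile(null, 95)),
        "upper_99": float(np.percentile(null, 99)),
    }


@dataclass
class PermutationResult:
    """Null distribution of ensemble accuracy and derived statistics."""

    null_accuracies: np.ndarray
    observed_accuracy: float
    p_value: float
    five_number_summary: dict
    upper_conf_levels: dict
    scheduled_boot_iterations: int
    master_seed: int
    permutation_seeds: list

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-permutation table (plot-ready)."""
        return pd.DataFrame(
            {
                "permutation": np.arange(1, self.null_accuracies.size + 1),
                "null_accuracy": self.null_accuracies,
            }
        )


def _perm_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=(1, index))
    return int(ss.generate_state(1)[0] % (2**31))


def permutation_test(
    data: LabeledDataset,
    observed: Ensemble,
    n_perm: int = 100,
    master_seed: int = 0,
    n_workers: int = 1,
) -> PermutationResult:
    """Build ``n_perm`` ensembles on label-shuffled copies of ``data``.

    The observed ensemble is passed in, not rebuilt, and its configuration
    snapshot drives every permuted rebuild — null and observed pipelines
    are identical except for the label shuffle. Failures are annotated
    with the permutation index.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cfg = observed.config_snapshot
    from .optimizer import OptimizerSettings
    from .svm_engine import HyperParamBounds

    settings = OptimizerSettings(**cfg["settings"])
    bounds = HyperParamBounds(**cfg["bounds"])
    nulls = np.empty(n_perm)
    seeds = [_perm_seed(master_seed, p) for p in range(n_perm)]
    scheduled = 0
    for p in range(n_perm):
        rng = np.random.default_rng(seeds[p])
        shuffled = permute_labels(data.labels, rng)
        permuted = LabeledDataset(
            matrix=data.matrix,
            labels=shuffled,
            sample_ids=data.sample_ids,
            variable_ids=data.variable_ids,
        )
        try:
            ens = build_ensemble(
                permuted,
                n_members=cfg["n_members"],
                test_fraction=cfg["test_fraction"],
                settings=settings,
                bounds=bounds,
                optimizer=cfg["optimizer"],
                scale=cfg["scale"],
                master_seed=seeds[p],
                n_workers=n_workers,
            )
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"permutation {p} failed: {exc}") from exc
        nulls[p] = ens.avg_test_accuracy
        for _member in ens.members:  # one objective of n_boot splits per member
            scheduled += settings.n_boot
    summary = null_summary(nulls) if n_perm >= 2 else {}
    return PermutationResult(
        null_accuracies=nulls,
        observed_accuracy=observed.avg_test_accuracy,
        p_value=empirical_p_value(observed.avg_test_accuracy, nulls),
        five_number_summary={
            k: summary[k] for k in ("min", "q1", "median", "q3", "max")
        }
        if summary
        else {},
        upper_conf_levels={95: summary["upper_95"], 99: summary["upper_99"]}
        if summary
        else {},
        scheduled_boot_iterations=scheduled,
        master_seed=master_seed,
        permutation_seeds=seeds,
    )
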