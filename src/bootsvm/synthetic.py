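"""Synthetic spectral-bin datasets for testing the pipeline end to end.

Real binned NMR matrices have a few properties the generator reproduces:
non-negative intensities, locally correlated variables (neighbouring bins
rise and fall together), and class differences confined to a subset of
informative bins. Noise is multivariate normal with block-diagonal
equicorrelation (within-block r = 0.6 by default); class signal is a mean
shift of ``effect_size`` within-class standard deviations on each class's
segment of the informative bins.

Two deterministic fixtures mirror common benchmark shapes: a two-class
18 x 189 matrix split 9/9, and a four-class 33 x 164 matrix (9/8/8/8)
whose fourth class deliberately overlaps the third, making it the hard
class to call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import LabeledDataset

__all__ = ["GeneratorSpec", "generate", "fixture_dataset_A", "fixture_dataset_B"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic spectral-matrix generator.

    n_per_class
        Samples per class, e.g. ``(9, 9)``.
    n_variables
        Total number of spectral bins.
    n_informative
        Bins carrying class signal (the first ``n_informative`` columns),
        divided contiguously among the classes.
    effect_size
        Between-class mean shift on a class's informative bins, in units
        of the within-class standard deviation. 0 = pure null.
    within_class_sd
        Noise scale of every bin.
    correlation_block_size
        Bins per equicorrelated noise block (within-block r = 0.6).
    seed
        Generator seed; equal specs produce bit-identical datasets.
    """

    n_per_class: tuple = (9, 9)
    n_variables: int = 189
    n_informative: int = 20
    effect_size: float = 1.0
    within_class_sd: float = 1.0
    correlation_block_size: int = 5
    block_correlation: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_class) < 2 or any(n < 2 for n in self.n_per_class):
            raise ValueError("need >= 2 classes with >= 2 samples each")
        if not 0 <= self.n_informative <= self.n_variables:
            raise ValueError("n_informative must lie in [0, n_variables]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.within_class_sd <= 0 or self.correlation_block_size < 1:
            raise ValueError("scale/block parameters must be positive")
        if not 0 <= self.block_correlation < 1:
            raise ValueError("block correlation must lie in [0, 1)")


def _class_shifts(spec: GeneratorSpec) -> np.ndarray:
    """Per-class mean-shift vectors over all variables.

    The informative bins are split contiguously into one segment per
    class; class c's mean is raised by effect_size * sd on segment c.
    Segments are disjoint, so every pair of classes differs on two
    segments.
    """
    n_classes = len(spec.n_per_class)
    shifts = np.zeros((n_classes, spec.n_variables))
    if spec.n_informative == 0 or spec.effect_size == 0:
        return shifts
    seg = np.array_split(np.arange(spec.n_informative), n_classes)
    amp = spec.effect_size * spec.within_class_sd
    for c in range(n_classes):
        shifts[c, seg[c]] = amp
    return shifts


def _block_noise(
    rng: np.random.Generator, n: int, p: int, block: int, r: float, sd: float
) -> np.ndarray:
    """Gaussian noise, equicorrelated (corr r) within contiguous blocks."""
    shared = rng.standard_normal((n, int(np.ceil(p / block))))
    shared = np.repeat(shared, block, axis=1)[:, :p]
    indiv = rng.standard_normal((n, p))
    return sd * (np.sqrt(r) * shared + np.sqrt(1.0 - r) * indiv)


def generate(spec: GeneratorSpec) -> LabeledDataset:
    """Draw one dataset from the generating model.

    The baseline intensity is lifted high enough (6 noise SDs above the
    largest class shift) that intensities are non-negative with
    overwhelming probability, mimicking binned spectra.
    """
    rng = np.random.default_rng(spec.seed)
    shifts = _class_shifts(spec)
    baseline = 6.0 * spec.within_class_sd + shifts.max()
    rows = []
    labels = []
    for c, n_c in enumerate(spec.n_per_class):
        noise = _block_noise(
            rng,
            n_c,
            spec.n_variables,
            spec.correlation_block_size,
            spec.block_correlation,
            spec.within_class_sd,
        )
        rows.append(baseline + shifts[c] + noise)
        labels.extend([f"class{c + 1}"] * n_c)
    return LabeledDataset(
        matrix=np.vstack(rows),
        labels=np.array(labels),
        variable_ids=np.array([f"bin{j}" for j in range(spec.n_variables)]),
    )


def fixture_dataset_A() -> LabeledDataset:
    """Two-class 18 x 189 fixture (9/9), strong but imperfect separation."""
    return generate(
        GeneratorSpec(
            n_per_class=(9, 9),
            n_variables=189,
            n_informative=20,
            effect_size=3.0,
            within_class_sd=1.0,
            correlation_block_size=5,
            seed=1189,
        )
    )


def fixture_dataset_B() -> LabeledDataset:
    """Four-class 33 x 164 fixture (9/8/8/8); class 4 overlaps class 3.

    Classes 1-3 get disjoint informative segments; class 4's shift is a
    60/40 blend of class 3's pattern and its own much weaker segment, so
    class 4 is genuinely confusable with class 3 while classes 1 and 2
    stay easy.
    """
    spec = GeneratorSpec(
        n_per_class=(9, 8, 8, 8),
        n_variables=164,
        n_informative=24,
        effect_size=3.0,
        within_class_sd=1.0,
        correlation_block_size=4,
        seed=33164,
    )
    rng = np.random.default_rng(spec.seed)
    shifts = _class_shifts(spec)
    # overlap: class 4 mostly mimics class 3
    shifts[3] = 0.6 * shifts[2] + 0.4 * shifts[3]
    baseline = 6.0 * spec.within_class_sd + shifts.max()
    rows = []
    labels = []
    for c, n_c in enumerate(spec.n_per_class):
        noise = _block_noise(
            rng,
            n_c,
            spec.n_variables,
            spec.correlation_block_size,
            spec.block_correlation,
            spec.within_class_sd,
        )
        rows.append(baseline + shifts[c] + noise)
        labels.extend([f"class{c + 1}"] * n_c)
    return LabeledDataset(
        matrix=np.vstack(rows),
        labels=np.array(labels),
        variable_ids=np.array([f"bin{j}" for j in range(spec.n_variables)]),
    )
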