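"""File I/O: CSV/TSV dataset loading, ensemble archives, run configuration.

The interchange format is a delimited matrix with one sample per row.
Labels come either from a named column of the same file or from a
separate single-column file aligned by row order (or by sample ID when
both files carry IDs). Ensembles are serialised as a zip archive holding
a JSON manifest (format version, configuration, seeds, metrics) plus the
pickled member models; the manifest makes every run reproducible from the
archive alone.
"""

from __future__ import annotations

import io as _io
import json
import pickle
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_model import DatasetError, LabeledDataset
from .ensemble import Ensemble
from .optimizer import OptimizerSettings
from .svm_engine import HyperParamBounds

__all__ = [
    "RunConfig",
    "read_dataset",
    "save_ensemble",
    "load_ensemble",
    "ArchiveError",
]

ARCHIVE_FORMAT_VERSION = 1


class ArchiveError(ValueError):
    """Raised on version mismatch or corrupted ensemble archives."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a build/permute run exactly."""

    test_fraction: float = 1.0 / 3.0
    n_members: int = 100
    n_boot: int = 100
    n_perm: int = 100
    optimizer: str = "simplex"
    k: int = 4
    alpha: float = 1.3
    tol: float = 1e-3
    max_iter: int = 100
    restarts: int = 3
    scale: bool = True
    log2C_min: float = -5.0
    log2C_max: float = 15.0
    log2gamma_min: float = -15.0
    log2gamma_max: float = 5.0
    master_seed: int = 0
    n_workers: int = 1
    output_dir: str = "."

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0,1)")
        for name in ("n_members", "n_boot", "n_perm", "n_workers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def settings(self) -> OptimizerSettings:
        return OptimizerSettings(
            k=self.k,
            alpha=self.alpha,
            tol=self.tol,
            max_iter=self.max_iter,
            restarts=self.restarts,
            n_boot=self.n_boot,
        )

    def bounds(self) -> HyperParamBounds:
        return HyperParamBounds(
            log2C_min=self.log2C_min,
            log2C_max=self.log2C_max,
            log2gamma_min=self.log2gamma_min,
            log2gamma_max=self.log2gamma_max,
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        return cls(**raw)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=None)
    if df.shape[0] == 0:
        raise DatasetError(f"{path}: no data rows (header-only or empty file)")
    return df


def read_dataset(
    matrix_path: str | Path,
    labels_path: str | Path | None = None,
    label_column: str | None = None,
    id_column: str | None = None,
) -> LabeledDataset:
    """Load a numeric sample x variable matrix plus class labels.

    Exactly one of ``labels_path`` (separate single-column file, aligned
    by row order or sample ID) or ``label_column`` (column of the matrix
    file) must be given. ``id_column`` names a sample-ID column; a
    leading non-numeric first column is also auto-detected as IDs.
    Non-numeric cells, row-count mismatches and duplicate IDs raise
    structured errors.
    """
    if (labels_path is None) == (label_column is None):
        raise DatasetError("provide exactly one of labels_path or label_column")
    df = _read_table(matrix_path)

    sample_ids = None
    if id_column is not None:
        if id_column not in df.columns:
            raise DatasetError(f"id column {id_column!r} not found")
        sample_ids = df[id_column].astype(str).to_numpy()
        df = df.drop(columns=[id_column])
    elif df.shape[1] and not pd.api.types.is_numeric_dtype(df.iloc[:, 0]):
        first = df.columns[0]
        if label_column is None or first != label_column:
            sample_ids = df[first].astype(str).to_numpy()
            df = df.drop(columns=[first])

    if label_column is not None:
        if label_column not in df.columns:
            raise DatasetError(f"label column {label_column!r} not found")
        labels = df[label_column].astype(str).to_numpy()
        df = df.drop(columns=[label_column])
    else:
        ldf = _read_table(labels_path)
        if ldf.shape[1] == 2 and sample_ids is not None:
            key = ldf.columns[0]
            lmap = dict(
                zip(ldf[key].astype(str), ldf[ldf.columns[1]].astype(str))
            )
            missing = [s for s in sample_ids if s not in lmap]
            if missing:
                raise DatasetError(
                    f"labels file lacks entries for sample IDs {missing[:5]}"
                )
            labels = np.array([lmap[s] for s in sample_ids])
        else:
            if ldf.shape[1] != 1:
                raise DatasetError(
                    f"labels file must have 1 column (or ID+label), "
                    f"got {ldf.shape[1]}"
                )
            if ldf.shape[0] != df.shape[0]:
                raise DatasetError(
                    f"labels file has {ldf.shape[0]} rows but the matrix "
                    f"has {df.shape[0]} samples"
                )
            labels = ldf.iloc[:, 0].astype(str).to_numpy()

    bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if bad:
        raise DatasetError(f"non-numeric matrix columns: {bad[:5]}")
    return LabeledDataset(
        matrix=df.to_numpy(dtype=float),
        labels=labels,
        sample_ids=sample_ids,
        variable_ids=np.asarray(df.columns.astype(str)),
    )


def save_ensemble(ens: Ensemble, path: str | Path) -> None:
    """Write a versioned zip archive: JSON manifest + pickled members."""
    manifest = {
        "format_version": ARCHIVE_FORMAT_VERSION,
        "n_members": ens.n_members,
        "master_seed": ens.master_seed,
        "config": ens.config_snapshot,
        "fused_vote_rule": ens.fused_vote_rule,
        "metrics": {
            "avg_test_accuracy": ens.avg_test_accuracy,
            "per_class_accuracy": {
                str(k): v for k, v in ens.per_class_accuracy.items()
            },
            "accuracy_vs_size": ens.accuracy_vs_size.tolist(),
        },
        "member_seeds": [m.seed for m in ens.members],
        "member_test_accuracies": [m.test_accuracy for m in ens.members],
        "index_convention": "0-based",
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))
        buf = _io.BytesIO()
        pickle.dump(ens, buf, protocol=pickle.HIGHEST_PROTOCOL)
        zf.writestr("ensemble.pkl", buf.getvalue())


def load_ensemble(path: str | Path) -> Ensemble:
    """Load an archive written by :func:`save_ensemble`.

    Round trip preserves predictions exactly. A manifest from a newer
    format version is refused rather than misread.
    """
    try:
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            version = manifest.get("format_version")
            if version != ARCHIVE_FORMAT_VERSION:
                raise ArchiveError(
                    f"archive format version {version} not supported "
                    f"(this build reads version {ARCHIVE_FORMAT_VERSION})"
                )
            ens = pickle.loads(zf.read("ensemble.pkl"))
    except (zipfile.BadZipFile, KeyError) as exc:
        raise ArchiveError(f"corrupted ensemble archive {path}: {exc}") from exc
    if ens.n_members != manifest["n_members"]:
        raise ArchiveError("manifest/member count mismatch")
    return ens
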