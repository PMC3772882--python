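"""Tabular and model I/O.

Feature tables are delimited text, one row per trial, last column the class
label; a header row is auto-detected.  Fitted models serialize to a
versioned JSON schema that round-trips at full double precision.  CSV
artifacts written by the CLI carry ``#``-prefixed metadata lines (seed,
config hash) that readers here skip transparently.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .csp import TrialArray
from .lslda import AugmentedWeights
from .zrule import ScoreDistribution, ZldaModel

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "save_model",
    "load_model",
    "write_table",
    "read_trial_dir",
    "write_trial_dir",
    "config_hash",
    "MODEL_SCHEMA_VERSION",
]

MODEL_SCHEMA_VERSION = 1


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_feature_table(
    path: str | Path, delimiter: str = ","
) -> tuple[np.ndarray, np.ndarray]:
    """Read a labelled feature table: numeric matrix plus class-name column.

    The last column is the label; every other cell must parse as a number.
    If any feature cell of the first non-comment row is non-numeric, that
    row is treated as a header.  Row order is preserved.
    """
    path = Path(path)
    lines = [
        ln
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise ValueError(f"empty feature table: {path}")
    first = lines[0].split(delimiter)
    has_header = len(first) > 1 and not all(_is_number(c) for c in first[:-1])
    df = pd.read_csv(
        _io.StringIO("\n".join(lines)),
        sep=delimiter,
        header=0 if has_header else None,
    )
    if df.shape[1] < 2:
        raise ValueError("feature table needs at least one feature and a label column")
    features = df.iloc[:, :-1]
    for col_pos, col in enumerate(features.columns):
        numeric = pd.to_numeric(features[col], errors="coerce")
        bad = numeric.isna() & features[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric feature cell at row {row}, column {col_pos} in {path}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ValueError(f"missing feature cell at row {row}, column {col_pos} in {path}")
    X = features.to_numpy(dtype=float)
    labels = df.iloc[:, -1].astype(str).to_numpy()
    return X, labels


def write_feature_table(
    path: str | Path,
    X: np.ndarray,
    labels: Sequence[str],
    delimiter: str = ",",
    metadata: dict[str, Any] | None = None,
) -> None:
    """Write features + label column, with optional ``#`` metadata lines."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    df["label"] = list(labels)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep=delimiter, index=False)


def save_model(
    model: ZldaModel, path: str | Path, metadata: dict[str, Any] | None = None
) -> None:
    """Serialize a fitted model to versioned JSON (full double precision)."""
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "bias": model.weights.bias,
        "weights": model.weights.weights.tolist(),
        "coding": list(model.coding),
        "classes": list(model.classes),
        "class1": {"mu": model.dist1.mu, "sigma": model.dist1.sigma, "n": model.dist1.n},
        "class2": {"mu": model.dist2.mu, "sigma": model.dist2.sigma, "n": model.dist2.n},
    }
    if metadata:
        doc["metadata"] = metadata
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_model(path: str | Path) -> ZldaModel:
    """Load a model saved by :func:`save_model`; rejects unknown schema versions."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt model file {path}: {exc}") from exc
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model schema version {version!r} "
            f"(this build reads version {MODEL_SCHEMA_VERSION})"
        )
    return ZldaModel(
        weights=AugmentedWeights(bias=doc["bias"], weights=np.asarray(doc["weights"])),
        dist1=ScoreDistribution(**doc["class1"]),
        dist2=ScoreDistribution(**doc["class2"]),
        coding=tuple(doc["coding"]),
        classes=tuple(doc["classes"]),
    )


def write_table(
    df: pd.DataFrame, path: str | Path, metadata: dict[str, Any] | None = None
) -> None:
    """Write a results DataFrame as CSV with ``#`` metadata header lines."""
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_trial_dir(path: str | Path, delimiter: str = ",") -> TrialArray:
    """Load a trial directory: ``manifest.csv`` plus per-trial numeric files.

    The manifest has columns ``file,label,fs``; each trial file is a
    channels x samples delimited matrix.  All trials must share fs and
    channel/sample counts.
    """
    path = Path(path)
    manifest = pd.read_csv(path / "manifest.csv", comment="#")
    for col in ("file", "label", "fs"):
        if col not in manifest.columns:
            raise ValueError(f"manifest missing column {col!r}")
    fs_values = manifest["fs"].unique()
    if len(fs_values) != 1:
        raise ValueError("all trials must share one sampling rate")
    data = np.stack(
        [
            np.loadtxt(path / row.file, delimiter=delimiter, ndmin=2)
            for row in manifest.itertuples()
        ]
    )
    return TrialArray(
        data=data, fs=float(fs_values[0]), labels=manifest["label"].astype(str).to_numpy()
    )


def write_trial_dir(trials: TrialArray, path: str | Path, delimiter: str = ",") -> None:
    """Write a TrialArray in the directory layout read by :func:`read_trial_dir`."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(trials.n_trials):
        name = f"trial_{i:04d}.csv"
        np.savetxt(path / name, trials.data[i], delimiter=delimiter)
        rows.append({"file": name, "label": trials.labels[i], "fs": trials.fs})
    pd.DataFrame(rows).to_csv(path / "manifest.csv", index=False)


def config_hash(config: dict[str, Any]) -> str:
    """Stable short hash of a run configuration, for output provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
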