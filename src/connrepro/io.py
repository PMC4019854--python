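"""Delimited-text I/O: matrix files and the dataset manifest.

Matrix files are square numeric tables, comma- or tab-delimited
(auto-detected), with optional first-row/first-column region labels; labels
``region_0001``... are generated when absent.  A manifest is a delimited
table with header columns ``file_path, subject_id, session_id, group``
mapping each matrix file to its cohort identity.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ConnectivityMatrix, validate_matrix

MANIFEST_COLUMNS = ("file_path", "subject_id", "session_id", "group")


def _detect_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    """Read a connectivity matrix from delimited text.

    Accepts a bare numeric table or one with a label header row and label
    index column.  Raises ``FileNotFoundError`` for a missing file and
    ``ValueError`` with distinct messages for non-square or non-numeric
    content; matrix invariants are validated on load.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"matrix file is empty: {path}")
    delim = _detect_delimiter(text.splitlines()[0])
    raw = pd.read_csv(
        _stdio.StringIO(text), header=None, sep=delim, dtype=str, keep_default_na=False
    )
    try:
        values = raw.to_numpy(dtype=float)
        labels = None
    except ValueError:
        # assume first row and column carry labels
        labels = [str(x) for x in raw.iloc[0, 1:]]
        try:
            values = raw.iloc[1:, 1:].to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"non-numeric matrix entries in {path}: {exc}") from None
    if values.shape[0] != values.shape[1]:
        raise ValueError(
            f"matrix file {path} is not square: shape {values.shape[0]}x{values.shape[1]}"
        )
    return validate_matrix(ConnectivityMatrix(weights=values, node_labels=labels))


def write_matrix(m: ConnectivityMatrix, path: str | Path) -> None:
    """Write a matrix as CSV with label header row and index column."""
    path = Path(path)
    frame = pd.DataFrame(m.weights, index=m.node_labels, columns=m.node_labels)
    frame.to_csv(path)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a dataset manifest.

    Relative ``file_path`` entries are resolved against the manifest's
    directory.  (subject_id, session_id, group) triples must be unique and
    every referenced file must exist.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    delim = _detect_delimiter(path.read_text().splitlines()[0])
    table = pd.read_csv(path, sep=delim, dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    triples = table[["subject_id", "session_id", "group"]]
    if triples.duplicated().any():
        dup = triples[triples.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicate (subject, session, group) triple in manifest: {dup}")
    base = path.parent
    resolved = []
    for fp in table["file_path"]:
        p = Path(fp)
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise FileNotFoundError(f"manifest references missing matrix file: {p}")
        resolved.append(str(p))
    table = table.assign(file_path=resolved)
    return table


def load_dataset(manifest_path: str | Path) -> list[ConnectivityMatrix]:
    """Load every matrix listed in a manifest, attaching its identity."""
    table = read_manifest(manifest_path)
    dataset = []
    for row in table.itertuples(index=False):
        m = read_matrix(row.file_path)
        m.subject_id = str(row.subject_id)
        m.session_id = str(row.session_id)
        m.group = str(row.group)
        dataset.append(m)
    return dataset


def write_dataset(dataset: list[ConnectivityMatrix], out_dir: str | Path) -> Path:
    """Write matrices plus a manifest.csv into ``out_dir``; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for m in dataset:
        name = f"{m.subject_id}_{m.session_id}_{m.group}.csv"
        write_matrix(m, out_dir / name)
        rows.append((name, m.subject_id, m.session_id, m.group))
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path
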