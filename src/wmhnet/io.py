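"""Readers for the delimited cohort formats written by :mod:`wmhnet.cohort`."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from wmhnet.cohort import SUBJECTS_HEADER, SubjectRecord
from wmhnet.preprocess import RoiTimeSeries

__all__ = ["read_subjects", "read_timeseries", "read_cohort", "read_node_labels"]

_INT_COLUMNS = ("pvh", "dwmh", "fazekas_total", "age", "education_years", "moca", "mmse")


def read_node_labels(path: str | Path) -> list[str]:
    labels = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    if not labels:
        raise ValueError(f"node-label file {path} is empty")
    return labels


def read_subjects(path: str | Path) -> pd.DataFrame:
    """Load and validate the subjects table (indexed by subject_id)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str, "sex": str}, float_precision="round_trip")
    missing = [c for c in SUBJECTS_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"subjects table {path} missing columns: {missing}")
    extra = [c for c in df.columns if c not in SUBJECTS_HEADER]
    if extra:
        raise ValueError(f"subjects table {path} has unknown columns: {extra}")
    for col in _INT_COLUMNS:
        values = df[col]
        if not np.issubdtype(values.dtype, np.number) or values.isna().any():
            bad = values[pd.to_numeric(values, errors="coerce").isna()].index.tolist()
            raise ValueError(f"non-numeric values in column {col!r} at rows {bad}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")
    return df.set_index("subject_id", drop=False)


def read_timeseries(path: str | Path, tr_seconds: float, node_labels: list[str] | None = None) -> RoiTimeSeries:
    """Load one T x N time-series CSV; column order must match the label file."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    try:
        data = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    labels = list(df.columns)
    if node_labels is not None and labels != list(node_labels):
        raise ValueError(
            f"{path} columns do not match the node-label file "
            f"({len(labels)} columns vs {len(node_labels)} labels)"
        )
    return RoiTimeSeries(data, tr_seconds, tuple(labels))


def read_cohort(directory: str | Path, tr_seconds: float = 2.0) -> list[SubjectRecord]:
    """Reconstruct SubjectRecords from a cohort directory."""
    directory = Path(directory)
    table = read_subjects(directory / "subjects.csv")
    label_file = directory / "node_labels.txt"
    labels = read_node_labels(label_file) if label_file.exists() else None
    records = []
    for _, row in table.iterrows():
        ts = read_timeseries(directory / row["timeseries_file"], tr_seconds, labels)
        records.append(
            SubjectRecord(
                subject_id=row["subject_id"],
                pvh_grade=int(row["pvh"]),
                dwmh_grade=int(row["dwmh"]),
                fazekas_total=int(row["fazekas_total"]),
                group=row["group"],
                wmh_volume=float(row["wmh_volume_ml"]),
                age=int(row["age"]),
                sex=row["sex"],
                education=int(row["education_years"]),
                moca=int(row["moca"]),
                mmse=int(row["mmse"]),
                timeseries=ts,
            )
        )
    return records
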