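"""Readers and writers for the plain-text formats used across the pipeline.

Matrices (connectivity, masks) are tab-separated grids with one header row
and one header column of region labels.  Parcel time series are written
regions x timepoints with the region label as the first column.  Subject
tables are CSV with at least ``subject_id`` and ``group`` columns.  The
packaged region table lists the 166 regions of the AAL3 parcellation in
standard consecutive atlas order; its MNI centroid columns are synthetic
placeholders (the ordering, which defines anatomical neighbourhood for the
cluster test, is the meaningful part).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_GROUPS = ("control", "depression")


def default_region_labels(n: int) -> list[str]:
    return [f"R{i + 1:03d}" for i in range(n)]


def write_matrix(path, matrix: np.ndarray, labels: list[str] | None = None) -> None:
    """Write a dense matrix as TSV with a header row and header column."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2-D")
    n_rows, n_cols = matrix.shape
    if labels is None:
        labels = default_region_labels(max(n_rows, n_cols))
    row_labels = labels[:n_rows]
    col_labels = labels[:n_cols]
    with open(path, "w") as fh:
        fh.write("\t".join([""] + list(col_labels)) + "\n")
        for lab, row in zip(row_labels, matrix):
            fh.write(lab + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_matrix(path, expect_symmetric: bool = False, atol: float = 1e-8):
    """Read a TSV matrix written by :func:`write_matrix`.

    Returns ``(matrix, row_labels)``.  Ragged rows and non-numeric cells
    raise ``ValueError`` with the offending line number.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln != ""]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    header = lines[0].split("\t")
    col_labels = header[1:]
    n_cols = len(col_labels)
    labels, rows = [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != n_cols + 1:
            raise ValueError(
                f"{path}: line {lineno}: expected {n_cols + 1} fields, got {len(parts)}"
            )
        labels.append(parts[0])
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
    matrix = np.array(rows, dtype=float)
    if expect_symmetric:
        if matrix.shape[0] != matrix.shape[1]:
            raise ValueError(f"{path}: expected square matrix, got {matrix.shape}")
        if labels != col_labels:
            raise ValueError(f"{path}: row and column labels disagree")
        if not np.allclose(matrix, matrix.T, atol=atol):
            raise ValueError(f"{path}: matrix not symmetric within {atol}")
    return matrix, labels


def write_timeseries(path, data: np.ndarray, labels: list[str]) -> None:
    """Write a regions x timepoints series, one region per labelled row."""
    data = np.asarray(data, dtype=float)
    with open(path, "w") as fh:
        fh.write("\t".join(["region"] + [f"t{k}" for k in range(data.shape[1])]) + "\n")
        for lab, row in zip(labels, data):
            fh.write(lab + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_timeseries(path):
    """Read a series written by :func:`write_timeseries` -> (data, labels)."""
    matrix, labels = read_matrix(path)
    return matrix, labels


def read_subject_table(path) -> pd.DataFrame:
    """Read and validate the subject table (CSV).

    Requires ``subject_id`` and ``group`` columns; ``group`` must be one of
    ``control``/``depression``.  An optional ``diagnosis`` column carries the
    clinical subgroup of the patients and feeds dummy-coded covariates.
    Row order in the file is preserved and defines the subject order used by
    every downstream stage.
    """
    df = pd.read_csv(path)
    return validate_subject_table(df)


def validate_subject_table(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise ValueError(f"subject table missing required column {col!r}")
    dupes = df["subject_id"][df["subject_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate subject ids: {sorted(set(dupes))}")
    bad = sorted(set(df["group"]) - set(VALID_GROUPS))
    if bad:
        raise ValueError(f"unknown group value(s) {bad}; expected {VALID_GROUPS}")
    return df.reset_index(drop=True)


def diagnosis_dummies(df: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code the patient diagnosis subgroups.

    One 0/1 column per diagnosis level observed among the depression group;
    the columns sum to the depression indicator.  Rank pruning against the
    group contrast happens later, when the design matrix is assembled.
    """
    if "diagnosis" not in df.columns:
        return pd.DataFrame(index=df.index)
    patient = df["group"] == "depression"
    levels = sorted(df.loc[patient, "diagnosis"].dropna().unique())
    out = {}
    for lev in levels:
        out[f"diagnosis_{lev}"] = ((df["diagnosis"] == lev) & patient).astype(float)
    return pd.DataFrame(out, index=df.index)


@dataclass
class RegionTable:
    """Atlas metadata: 1-based index, label, and MNI centroid per region.

    Ascending atlas index order defines the anatomical neighbourhood used by
    the node-cluster permutation test.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        required = {"index", "label", "x", "y", "z"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"region table missing columns {sorted(missing)}")
        idx = self.frame["index"].to_numpy()
        if len(set(idx)) != len(idx):
            raise ValueError("region table has duplicate atlas indices")
        if not np.all(np.diff(idx) > 0):
            raise ValueError("region table atlas indices must be sorted ascending")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def labels(self) -> list[str]:
        return list(self.frame["label"])

    @property
    def coordinates(self) -> np.ndarray:
        return self.frame[["x", "y", "z"]].to_numpy(dtype=float)

    @classmethod
    def read(cls, path) -> "RegionTable":
        return cls(pd.read_csv(path))

    def write(self, path) -> None:
        self.frame.to_csv(path, index=False)


def load_aal3() -> RegionTable:
    """Load the packaged 166-region AAL3 table (synthetic centroids)."""
    ref = importlib.resources.files("fconn.data").joinpath("aal3_synthetic.csv")
    with importlib.resources.as_file(ref) as path:
        return RegionTable.read(path)
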