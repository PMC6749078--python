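"""Reading and writing the delimited-text formats used throughout the pipeline.

All matrices travel as TSV with row/column labels; model objects as JSON.
Floats are printed with 10 significant digits so a write/read round trip is
value-identical at that precision.
"""

from __future__ import annotations

import dataclasses
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

FLOAT_FMT = "%.10g"


@dataclasses.dataclass
class LabeledMatrix:
    """A numeric matrix with row and column labels.

    Connectivity matrices are square and symmetric with a zero diagonal;
    rectangular matrices (e.g. window x region sequences) carry arbitrary
    labels on each axis.
    """

    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("LabeledMatrix requires a 2-D array")
        if len(self.row_labels) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.row_labels)} row labels for {self.values.shape[0]} rows"
            )
        if len(self.col_labels) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.col_labels)} column labels for {self.values.shape[1]} columns"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def require_square_symmetric(self, atol: float = 1e-12) -> None:
        if self.values.shape[0] != self.values.shape[1]:
            raise ValueError(
                f"square matrix required, got shape {self.values.shape}"
            )
        if not np.allclose(self.values, self.values.T, atol=atol):
            raise ValueError("matrix is not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)


def write_matrix(mat: LabeledMatrix, path: str | Path) -> None:
    """Write a labeled matrix as TSV (labels in header and first column)."""
    mat.to_frame().to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_matrix(path: str | Path, square: bool = False) -> LabeledMatrix:
    """Read a labeled TSV matrix; with ``square=True`` enforce symmetry."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in matrix: {exc}") from exc
    mat = LabeledMatrix(values, [str(i) for i in df.index], [str(c) for c in df.columns])
    if square:
        mat.require_square_symmetric()
    return mat


def read_timeseries(path: str | Path, tr_s: float):
    """Read a volumes x regions TSV with a header row of region labels.

    Returns a :class:`~metastate.netbuild.RoiTimeSeries`. Rejects files without
    a header, with fewer than two regions, or with any non-numeric/NaN cell
    (named by row and column in the error).
    """
    from .netbuild import RoiTimeSeries  # local import avoids a cycle

    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    df = pd.read_csv(path, sep="\t")
    labels = [str(c) for c in df.columns]
    numeric_header = True
    for lab in labels:
        try:
            float(lab)
        except ValueError:
            numeric_header = False
            break
    if numeric_header:
        raise ValueError(f"{path}: missing header row of region labels")
    if len(labels) < 2:
        raise ValueError(
            f"{path}: only {len(labels)} region column; a network needs >= 2 regions"
        )
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(coerced.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: non-numeric or missing value at volume {r + 1}, region '{labels[c]}'"
        )
    return RoiTimeSeries(signal=coerced.to_numpy(dtype=float), tr_s=tr_s, labels=labels)


def write_timeseries(signal: np.ndarray, labels: list[str], path: str | Path) -> None:
    pd.DataFrame(signal, columns=labels).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def read_structural_network(path: str | Path) -> LabeledMatrix:
    """Read a weighted structural network from either a labeled square TSV
    or a 3-column (region_i, region_j, weight) edge list."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] == 3:
        src, dst, w = df.columns
        weights = pd.to_numeric(df[w], errors="coerce")
        if weights.isna().any():
            raise ValueError(f"{path}: non-numeric edge weight")
        labels = sorted(set(df[src].astype(str)) | set(df[dst].astype(str)))
        idx = {lab: i for i, lab in enumerate(labels)}
        A = np.zeros((len(labels), len(labels)))
        for a, b, wt in zip(df[src].astype(str), df[dst].astype(str), weights):
            if a == b:
                raise ValueError(f"{path}: self-loop on '{a}'")
            A[idx[a], idx[b]] = A[idx[b], idx[a]] = float(wt)
        return LabeledMatrix(A, labels, labels)
    mat = read_matrix(path, square=True)
    return mat


def read_fd(path: str | Path) -> np.ndarray:
    """Read a single-column framewise-displacement vector (mm per volume)."""
    arr = np.loadtxt(path, ndmin=1)
    if arr.ndim != 1:
        raise ValueError(f"{path}: FD file must hold a single column")
    return arr


def frame_to_tsv_bytes(df: pd.DataFrame, index: bool = True) -> bytes:
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=index, float_format=FLOAT_FMT)
    return buf.getvalue().encode()
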