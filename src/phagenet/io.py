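"""Reading and writing host-range matrices, edge lists and corpus metadata.

A host-range matrix records which phages lyse which bacterial strains.  The
canonical in-memory orientation is rows = bacteria, columns = phages; files
whose rows are phages are transposed on read.  Quantitative lysis scores
(spot intensities, EOP values) are binarized with a configurable threshold:
any value strictly greater than the threshold counts as a lytic interaction.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HostRangeMatrix",
    "DatasetMetadata",
    "MatrixParseError",
    "DuplicateLabelError",
    "read_matrix",
    "matrix_from_frame",
    "write_edge_list",
    "read_edge_list",
    "load_table1_fixture",
]

_DELIMITERS = "\t,;"


class MatrixParseError(ValueError):
    """Raised when a delimited matrix file cannot be parsed."""


class DuplicateLabelError(MatrixParseError):
    """Raised when strain or phage identifiers are duplicated.

    Duplicates are an error rather than being merged: merging rows or
    columns would change node degrees and hence every importance score
    computed downstream.
    """


@dataclass(frozen=True)
class HostRangeMatrix:
    """Binary (or binarized quantitative) bacteria x phage lysis matrix.

    Parameters
    ----------
    bacteria_ids
        Strain labels, one per row.
    phage_ids
        Phage labels, one per column.
    values
        Raw numeric lysis values, shape ``(n_bacteria, n_phages)``.
    threshold
        Binarization cut-off; cells strictly greater than it are lytic.
    """

    bacteria_ids: tuple[str, ...]
    phage_ids: tuple[str, ...]
    values: np.ndarray
    threshold: float = 0.0
    binary: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "bacteria_ids", tuple(str(b) for b in self.bacteria_ids))
        object.__setattr__(self, "phage_ids", tuple(str(p) for p in self.phage_ids))
        _check_axis(self.bacteria_ids, "bacteria")
        _check_axis(self.phage_ids, "phage")
        if values.ndim != 2 or values.shape != (len(self.bacteria_ids), len(self.phage_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.bacteria_ids)} bacteria x {len(self.phage_ids)} phages"
            )
        if np.any(values < 0):
            raise ValueError("lysis values must be non-negative")
        object.__setattr__(
            self, "binary", (values > self.threshold).astype(np.int8)
        )

    @property
    def n_bacteria(self) -> int:
        return len(self.bacteria_ids)

    @property
    def n_phages(self) -> int:
        return len(self.phage_ids)

    @property
    def n_interactions(self) -> int:
        """Number of lytic cells in the binarized view."""
        return int(self.binary.sum())

    def binarized(self) -> "HostRangeMatrix":
        """Return a matrix whose raw values are the 0/1 binarized view."""
        return HostRangeMatrix(
            self.bacteria_ids, self.phage_ids, self.binary.astype(float), threshold=0.0
        )

    def transpose(self) -> "HostRangeMatrix":
        return HostRangeMatrix(
            self.phage_ids, self.bacteria_ids, self.values.T, threshold=self.threshold
        )

    def to_frame(self, binary: bool = False) -> pd.DataFrame:
        data = self.binary if binary else self.values
        return pd.DataFrame(
            data, index=list(self.bacteria_ids), columns=list(self.phage_ids)
        )


@dataclass(frozen=True)
class DatasetMetadata:
    """One row of the published host-range corpus summary."""

    dataset_name: str
    n_hosts: int
    n_phages: int
    matrix_size: int

    def __post_init__(self) -> None:
        if self.matrix_size != self.n_hosts * self.n_phages:
            raise ValueError(
                f"{self.dataset_name}: matrix_size {self.matrix_size} != "
                f"{self.n_hosts} x {self.n_phages}"
            )


def _check_axis(labels: Sequence[str], axis: str) -> None:
    if len(labels) == 0:
        raise ValueError(f"empty {axis} axis")
    if any(not lab.strip() for lab in labels):
        raise ValueError(f"empty {axis} label")
    seen: set[str] = set()
    dups = [lab for lab in labels if lab in seen or seen.add(lab)]  # type: ignore[func-returns-value]
    if dups:
        raise DuplicateLabelError(f"duplicate {axis} labels: {sorted(set(dups))}")


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=_DELIMITERS).delimiter
    except csv.Error:
        return "\t"


def read_matrix(
    path: str | Path,
    orientation: Literal["rows_are_bacteria", "rows_are_phages"] = "rows_are_bacteria",
    threshold: float = 0.0,
    delimiter: str | None = None,
) -> HostRangeMatrix:
    """Read a delimited host-range matrix file.

    The file must have one header row of column labels and one leading
    column of row labels.  The delimiter is auto-detected among tab, comma
    and semicolon unless given explicitly.

    Parameters
    ----------
    path
        Delimited text file, UTF-8.
    orientation
        ``rows_are_bacteria`` (canonical) or ``rows_are_phages`` (the
        matrix is transposed after reading).
    threshold
        Cells strictly greater than this binarize to lytic.  The default 0
        means any positive lysis score counts.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    sep = delimiter or _sniff_delimiter(text[:4096])
    # pandas would silently rename duplicate header labels; check them raw
    header = text.splitlines()[0].split(sep)[1:] if text else []
    dup_cols = {c for c in header if header.count(c) > 1}
    if dup_cols:
        raise DuplicateLabelError(f"{path}: duplicate column labels: {sorted(dup_cols)}")
    try:
        frame = pd.read_csv(
            _io.StringIO(text),
            sep=sep,
            index_col=0,
            header=0,
            engine="python",
            on_bad_lines="error",
        )
    except pd.errors.ParserError as exc:
        raise MatrixParseError(f"{path}: {exc}") from exc
    if frame.shape[1] == 0:
        raise MatrixParseError(f"{path}: no data columns (delimiter {sep!r})")
    return matrix_from_frame(frame, orientation=orientation, threshold=threshold, source=str(path))


def matrix_from_frame(
    frame: pd.DataFrame,
    orientation: Literal["rows_are_bacteria", "rows_are_phages"] = "rows_are_bacteria",
    threshold: float = 0.0,
    source: str = "<frame>",
) -> HostRangeMatrix:
    """Build a :class:`HostRangeMatrix` from a labelled DataFrame."""
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.isna().stack()
        row, col = bad[bad].index[0]
        raise MatrixParseError(
            f"{source}: non-numeric cell at row {row!r}, column {col!r}"
        )
    row_ids = [str(i) for i in frame.index]
    col_ids = [str(c) for c in frame.columns]
    if orientation == "rows_are_bacteria":
        bacteria, phages, values = row_ids, col_ids, numeric.to_numpy(dtype=float)
    elif orientation == "rows_are_phages":
        bacteria, phages, values = col_ids, row_ids, numeric.to_numpy(dtype=float).T
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return HostRangeMatrix(tuple(bacteria), tuple(phages), values, threshold=threshold)


def write_matrix(matrix: HostRangeMatrix, path: str | Path, binary: bool = True) -> None:
    """Write a matrix as a TSV file in canonical orientation."""
    frame = matrix.to_frame(binary=binary)
    frame.to_csv(path, sep="\t", index_label="bacterium")


def write_edge_list(matrix: HostRangeMatrix, path: str | Path) -> None:
    """Write one ``phage<TAB>bacterium`` row per lytic interaction.

    Phage comes first because edges run phage -> bacterium in the directed
    infection network.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("phage\tbacterium\n")
        rows, cols = np.nonzero(matrix.binary)
        for b_idx, p_idx in zip(rows, cols):
            fh.write(f"{matrix.phage_ids[p_idx]}\t{matrix.bacteria_ids[b_idx]}\n")


def read_edge_list(
    path: str | Path,
    bacteria_ids: Iterable[str] | None = None,
    phage_ids: Iterable[str] | None = None,
) -> HostRangeMatrix:
    """Rebuild a binary matrix from a phage/bacterium edge list.

    Node identifier lists may be supplied to recover nodes with no edges
    (resistant bacteria, non-infecting phages) and a fixed ordering;
    otherwise both axes use first-appearance order from the file.
    """
    edges = pd.read_csv(path, sep="\t", dtype=str)
    if list(edges.columns[:2]) != ["phage", "bacterium"]:
        raise MatrixParseError(f"{path}: expected columns 'phage', 'bacterium'")
    bacteria = list(dict.fromkeys(bacteria_ids)) if bacteria_ids is not None else list(
        dict.fromkeys(edges["bacterium"])
    )
    phages = list(dict.fromkeys(phage_ids)) if phage_ids is not None else list(
        dict.fromkeys(edges["phage"])
    )
    b_index = {b: i for i, b in enumerate(bacteria)}
    p_index = {p: j for j, p in enumerate(phages)}
    values = np.zeros((len(bacteria), len(phages)))
    for phage, bacterium in edges.itertuples(index=False):
        try:
            values[b_index[bacterium], p_index[phage]] = 1.0
        except KeyError as exc:
            raise MatrixParseError(f"{path}: edge references unknown node {exc}") from exc
    return HostRangeMatrix(tuple(bacteria), tuple(phages), values)


def load_table1_fixture() -> list[DatasetMetadata]:
    """Load the packaged 50-dataset corpus metadata table.

    Each record gives a published host-range study, its number of bacterial
    hosts and phages, and the matrix size (hosts x phages).
    """
    ref = resources.files("phagenet.data").joinpath("table1_metadata.tsv")
    try:
        with ref.open("r", encoding="utf-8") as fh:
            frame = pd.read_csv(fh, sep="\t")
    except FileNotFoundError as exc:
        raise RuntimeError("packaged corpus metadata fixture is missing") from exc
    records = [
        DatasetMetadata(
            dataset_name=row.dataset,
            n_hosts=int(row.n_hosts),
            n_phages=int(row.n_phages),
            matrix_size=int(row.matrix_size),
        )
        for row in frame.itertuples(index=False)
    ]
    if len(records) != 50:
        raise RuntimeError(
            f"corpus metadata fixture is corrupt: expected 50 rows, found {len(records)}"
        )
    return records
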