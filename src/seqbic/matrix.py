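"""Domain types and readers/writers for expression matrices and bicluster sets.

The in-memory container for an expression matrix is a labelled real-valued
array with two boolean masks: one for values missing in the source data and
one for values masked out as outliers during pre-processing.  Biclusters are
index-based internally (0-based row/column indices into the matrix); every
serialised representation uses labels only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

DEFAULT_MISSING_TOKENS = frozenset({"", "NA", "NaN", "nan", "?"})


class MatrixFormatError(ValueError):
    """Raised for malformed delimited matrix files."""


@dataclass
class ExpressionMatrix:
    """Labelled real-valued matrix with missing and outlier masks.

    Parameters
    ----------
    values : (n, m) float array; entries under either mask are unusable and
        their stored value is arbitrary (NaN after reading).
    row_labels, col_labels : unique identifiers per dimension.
    missing_mask : True where the source had no usable value.
    outlier_mask : True where a value was masked during pre-processing;
        disjoint from ``missing_mask``.
    """

    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    missing_mask: np.ndarray = None
    outlier_mask: np.ndarray = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        n, m = self.values.shape
        self.row_labels = [str(r) for r in self.row_labels]
        self.col_labels = [str(c) for c in self.col_labels]
        if len(self.row_labels) != n or len(self.col_labels) != m:
            raise ValueError("label counts must match value dimensions")
        if len(set(self.row_labels)) != n:
            raise ValueError("row labels must be unique")
        if len(set(self.col_labels)) != m:
            raise ValueError("column labels must be unique")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.outlier_mask is None:
            self.outlier_mask = np.zeros((n, m), dtype=bool)
        self.outlier_mask = np.asarray(self.outlier_mask, dtype=bool)
        if self.missing_mask.shape != (n, m) or self.outlier_mask.shape != (n, m):
            raise ValueError("masks must match value dimensions")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def unusable_mask(self) -> np.ndarray:
        """Cells excluded from downstream computation (missing or outlier)."""
        return self.missing_mask | self.outlier_mask

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            list(self.row_labels),
            list(self.col_labels),
            self.missing_mask.copy(),
            self.outlier_mask.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)
        return df.mask(self.unusable_mask)

    def transpose(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.T.copy(),
            list(self.col_labels),
            list(self.row_labels),
            self.missing_mask.T.copy(),
            self.outlier_mask.T.copy(),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))


def read_matrix(
    path: str | Path,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    sep: str | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression matrix (genes x conditions).

    First row holds column labels; the first field of every subsequent row is
    the row label.  Cells equal to a missing token (default "", "NA", "NaN",
    "?") set the missing mask; everything else must parse as a number.
    """
    path = Path(path)
    missing = {t for t in missing_tokens}
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        raise MatrixFormatError(f"{path}: empty file")
    if sep is None:
        sep = "\t" if "\t" in lines[0] else ","
    header = lines[0].split(sep)
    col_labels = [h.strip() for h in header[1:]]
    if len(lines) < 2:
        raise MatrixFormatError(f"{path}: no data rows")
    m = len(col_labels)
    row_labels: list[str] = []
    values = np.empty((len(lines) - 1, m), dtype=float)
    miss = np.zeros((len(lines) - 1, m), dtype=bool)
    for i, line in enumerate(lines[1:]):
        fields = line.split(sep)
        if len(fields) != m + 1:
            raise MatrixFormatError(
                f"{path}: row {i + 2} has {len(fields) - 1} cells, expected {m}"
            )
        row_labels.append(fields[0].strip())
        for j, tok in enumerate(fields[1:]):
            tok = tok.strip()
            if tok in missing:
                values[i, j] = np.nan
                miss[i, j] = True
            else:
                try:
                    values[i, j] = float(tok)
                except ValueError as exc:
                    raise MatrixFormatError(
                        f"{path}: non-numeric value {tok!r} at row "
                        f"{row_labels[-1]!r}, column {col_labels[j]!r}"
                    ) from exc
    return ExpressionMatrix(values, row_labels, col_labels, miss)


def write_matrix(matrix: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a matrix as delimited text; unusable cells are written as NA."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(sep.join([""] + matrix.col_labels) + "\n")
        bad = matrix.unusable_mask
        for i, rl in enumerate(matrix.row_labels):
            cells = [
                "NA" if bad[i, j] else repr(float(matrix.values[i, j]))
                for j in range(matrix.n_cols)
            ]
            fh.write(sep.join([rl] + cells) + "\n")


# ---------------------------------------------------------------------------
# Biclusters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Bicluster:
    """A submatrix (row subset, column subset) with a linear column order.

    ``permutation`` is a tuple of tie groups: each group is a tuple of column
    indices whose values co-occur (share a symbol); groups are ordered by
    increasing value.  ``signs`` maps each row of ``rows`` to +1/-1; rows with
    -1 participate through their negated profile (symmetric expression).
    """

    rows: frozenset[int]
    cols: frozenset[int]
    permutation: tuple[tuple[int, ...], ...]
    signs: tuple[int, ...] | None = None

    def __post_init__(self):
        if not self.rows or not self.cols:
            raise ValueError("bicluster rows and cols must be non-empty")
        perm_cols = [c for grp in self.permutation for c in grp]
        if sorted(perm_cols) != sorted(self.cols):
            raise ValueError("permutation must be a bijection over cols")
        if self.signs is not None:
            if len(self.signs) != len(self.rows):
                raise ValueError("signs must align with rows")
            if any(s not in (-1, 1) for s in self.signs):
                raise ValueError("signs must be -1 or +1")

    @property
    def support(self) -> int:
        return len(self.rows)

    @property
    def area(self) -> int:
        return len(self.rows) * len(self.cols)

    @property
    def row_list(self) -> list[int]:
        return sorted(self.rows)

    @property
    def col_order(self) -> list[int]:
        """Columns flattened in permutation order (ties in index order)."""
        return [c for grp in self.permutation for c in sorted(grp)]

    def sign_of(self, row: int) -> int:
        if self.signs is None:
            return 1
        return self.signs[self.row_list.index(row)]

    def canonical_signs(self) -> tuple[int, ...] | None:
        """Sign vector with the first (lowest-index) row fixed to +1.

        A sign vector and its global negation describe the same symmetry
        class; this picks a canonical representative.
        """
        if self.signs is None:
            return None
        if self.signs[0] == -1:
            return tuple(-s for s in self.signs)
        return self.signs


@dataclass
class BiclusterSet:
    """Ordered, possibly overlapping collection of biclusters + provenance."""

    biclusters: list[Bicluster] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.biclusters)

    def __iter__(self) -> Iterator[Bicluster]:
        return iter(self.biclusters)

    def __getitem__(self, i: int) -> Bicluster:
        return self.biclusters[i]

    def coverage(self, shape: tuple[int, int]) -> float:
        """Fraction of matrix cells covered by the union of biclusters."""
        covered = np.zeros(shape, dtype=bool)
        for b in self.biclusters:
            covered[np.ix_(sorted(b.rows), sorted(b.cols))] = True
        return float(covered.sum()) / (shape[0] * shape[1])

    def summary(self) -> str:
        lines = [f"{len(self.biclusters)} biclusters"]
        for k, b in enumerate(self.biclusters):
            lines.append(
                f"  #{k}: {len(b.rows)} rows x {len(b.cols)} cols"
                + ("" if b.signs is None else " (signed)")
            )
        return "\n".join(lines)


def _bicluster_to_obj(b: Bicluster, row_labels: list[str], col_labels: list[str]) -> dict:
    rows = b.row_list
    obj = {
        "rows": [row_labels[i] for i in rows],
        "columns": [[col_labels[c] for c in sorted(g)] for g in b.permutation],
        "support": b.support,
    }
    if b.signs is not None:
        obj["signs"] = list(b.signs)
    return obj


def _bicluster_from_obj(obj: dict, row_index: dict, col_index: dict) -> Bicluster:
    rows = frozenset(row_index[r] for r in obj["rows"])
    perm = tuple(tuple(sorted(col_index[c] for c in grp)) for grp in obj["columns"])
    cols = frozenset(c for grp in perm for c in grp)
    signs = tuple(obj["signs"]) if "signs" in obj else None
    return Bicluster(rows, cols, perm, signs)


def write_biclusters(
    bset: BiclusterSet,
    path: str | Path,
    row_labels: Sequence[str],
    col_labels: Sequence[str],
    format: str = "json",
) -> None:
    """Serialise a bicluster set.

    ``json`` writes a machine-readable document that round-trips through
    :func:`read_biclusters`.  ``text`` writes one human-readable block per
    bicluster with row labels, column labels in permutation order (tie groups
    in parentheses), signs and support.
    """
    path = Path(path)
    row_labels = [str(r) for r in row_labels]
    col_labels = [str(c) for c in col_labels]
    if format == "json":
        doc = {
            "provenance": bset.provenance,
            "row_labels": row_labels,
            "col_labels": col_labels,
            "biclusters": [
                _bicluster_to_obj(b, row_labels, col_labels) for b in bset.biclusters
            ],
        }
        path.write_text(json.dumps(doc, indent=1, default=str) + "\n")
    elif format == "text":
        with path.open("w") as fh:
            fh.write(f"# biclusters: {len(bset.biclusters)}\n")
            for k, b in enumerate(bset.biclusters):
                fh.write(f"\n## bicluster {k} ({b.support} rows)\n")
                fh.write("rows: " + " ".join(row_labels[i] for i in b.row_list) + "\n")
                parts = []
                for grp in b.permutation:
                    names = [col_labels[c] for c in sorted(grp)]
                    parts.append(names[0] if len(names) == 1 else "(" + " ".join(names) + ")")
                fh.write("columns: " + " ".join(parts) + "\n")
                if b.signs is not None:
                    fh.write("signs: " + " ".join(str(s) for s in b.signs) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_biclusters(path: str | Path) -> tuple[BiclusterSet, list[str], list[str]]:
    """Read a JSON bicluster document written by :func:`write_biclusters`."""
    doc = json.loads(Path(path).read_text())
    row_labels = doc["row_labels"]
    col_labels = doc["col_labels"]
    row_index = {r: i for i, r in enumerate(row_labels)}
    col_index = {c: j for j, c in enumerate(col_labels)}
    bics = [_bicluster_from_obj(o, row_index, col_index) for o in doc["biclusters"]]
    return BiclusterSet(bics, doc.get("provenance", {})), row_labels, col_labels
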