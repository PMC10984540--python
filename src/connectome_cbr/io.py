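"""Reading, validating and vectorizing structural connectivity data.

A structural connectome is stored per subject as a square symmetric
nonnegative matrix of connection strengths (e.g. streamline counts) over a
fixed parcellation.  For the regression analysis all subjects' matrices are
vectorized (strict upper triangle, lexicographic edge order) and stacked
into the n-subjects x m-edges design matrix ``A``; the cohort metadata
table carries the attribute vector ``b`` (age or an intelligence composite
score per subject).

Two plain-text dialects are supported:

``square_csv``
    A header row of ROI labels followed by one comma-separated numeric row
    per ROI.

``edge_list``
    Whitespace-separated ``roi_a roi_b weight`` lines, one undirected edge
    per line; absent pairs are zero.

Asymmetric input is rejected rather than symmetrized; nonzero diagonal
entries (self-loops emitted by some tools) are zeroed with a warning.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: absolute tolerance for the symmetry check on loaded matrices
SYMMETRY_ATOL = 1e-8

#: canonical cohort metadata columns (extra columns are preserved, ignored)
COHORT_COLUMNS = ("subject_id", "sex", "age", "intel_total", "intel_fluid", "intel_cryst")


class ConnectomeValidationError(ValueError):
    """Raised when a connectivity matrix or cohort table violates its contract."""


@dataclass
class ConnectivityMatrix:
    """A validated square, symmetric, nonnegative connectivity matrix.

    Parameters
    ----------
    subject_id :
        Opaque subject identifier.
    weights :
        ``(n_rois, n_rois)`` array; symmetric within :data:`SYMMETRY_ATOL`,
        all entries finite and >= 0, zero diagonal after validation.
    roi_labels :
        Ordered ROI label list defining row/column order.
    parcellation_label :
        Free-text label for the parcellation (e.g. ``"379"``).
    """

    subject_id: str
    weights: np.ndarray
    roi_labels: tuple[str, ...]
    parcellation_label: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        self.roi_labels = tuple(str(r) for r in self.roi_labels)
        n = len(self.roi_labels)
        if w.ndim != 2 or w.shape != (n, n):
            raise ConnectomeValidationError(
                f"subject {self.subject_id!r}: weights must be {n}x{n}, got {w.shape}"
            )
        if not np.all(np.isfinite(w)):
            raise ConnectomeValidationError(
                f"subject {self.subject_id!r}: non-finite weight encountered"
            )
        if np.any(w < 0):
            i, j = np.unravel_index(int(np.argmin(w)), w.shape)
            raise ConnectomeValidationError(
                f"subject {self.subject_id!r}: negative weight {w[i, j]} at "
                f"({self.roi_labels[i]}, {self.roi_labels[j]})"
            )
        asym = np.abs(w - w.T)
        if asym.size and asym.max() > SYMMETRY_ATOL:
            i, j = np.unravel_index(int(np.argmax(asym)), asym.shape)
            raise ConnectomeValidationError(
                f"subject {self.subject_id!r}: asymmetry {asym[i, j]:.3g} at pair "
                f"({self.roi_labels[i]}, {self.roi_labels[j]}) exceeds tolerance "
                f"{SYMMETRY_ATOL}"
            )
        if np.any(np.diag(w) != 0):
            logger.warning(
                "subject %r: nonzero diagonal entries zeroed (self-loops dropped)",
                self.subject_id,
            )
            w = w.copy()
            np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)


@dataclass
class DesignMatrix:
    """Stacked vectorized connectomes: rows are subjects, columns are edges.

    ``edge_index`` lists the ``(roi_a, roi_b)`` label pairs, strictly
    lexicographic by ROI *position* (the strict upper triangle), so
    ``m = n_rois * (n_rois - 1) / 2``.
    """

    values: np.ndarray
    edge_index: tuple[tuple[str, str], ...]
    subject_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.edge_index = tuple((str(a), str(b)) for a, b in self.edge_index)
        self.subject_order = tuple(str(s) for s in self.subject_order)
        n, m = self.values.shape
        if n != len(self.subject_order):
            raise ConnectomeValidationError(
                f"design matrix has {n} rows but {len(self.subject_order)} subjects"
            )
        if m != len(self.edge_index):
            raise ConnectomeValidationError(
                f"design matrix has {m} columns but {len(self.edge_index)} edges"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]


def edge_index_for(roi_labels: Sequence[str]) -> tuple[tuple[str, str], ...]:
    """Edge ordering for a parcellation: strict upper triangle, row-major."""
    labels = [str(r) for r in roi_labels]
    iu, ju = np.triu_indices(len(labels), k=1)
    return tuple((labels[i], labels[j]) for i, j in zip(iu, ju))


def vectorize(matrix: ConnectivityMatrix) -> np.ndarray:
    """Return the strict-upper-triangle edge weights in canonical edge order.

    The result has length ``n_rois * (n_rois - 1) / 2`` and matches
    :func:`edge_index_for` applied to the matrix's ROI labels.
    """
    iu, ju = np.triu_indices(matrix.n_rois, k=1)
    return matrix.weights[iu, ju].copy()


def materialize(
    edge_vector: np.ndarray, roi_labels: Sequence[str], subject_id: str = ""
) -> ConnectivityMatrix:
    """Inverse of :func:`vectorize`: rebuild the symmetric matrix from edges."""
    labels = tuple(str(r) for r in roi_labels)
    n = len(labels)
    vec = np.asarray(edge_vector, dtype=float)
    m = n * (n - 1) // 2
    if vec.shape != (m,):
        raise ConnectomeValidationError(
            f"edge vector has length {vec.shape}, expected ({m},) for {n} ROIs"
        )
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    w[iu, ju] = vec
    w[ju, iu] = vec
    return ConnectivityMatrix(subject_id=subject_id, weights=w, roi_labels=labels)


def read_matrix(
    path: str | Path,
    dialect: Literal["square_csv", "edge_list"] = "square_csv",
    roi_labels: Sequence[str] | None = None,
    subject_id: str | None = None,
) -> ConnectivityMatrix:
    """Read one subject's connectivity matrix from a plain-text file.

    Parameters
    ----------
    path :
        File to read; the stem is used as ``subject_id`` unless given.
    dialect :
        ``"square_csv"`` (header of ROI labels + numeric rows) or
        ``"edge_list"`` (``roi_a roi_b weight`` lines).
    roi_labels :
        Required for ``edge_list`` (the file need not mention every ROI);
        ignored for ``square_csv``.

    Raises
    ------
    ConnectomeValidationError
        On asymmetry beyond tolerance, negative weights, or (edge_list)
        unknown ROI labels or duplicate pairs.
    """
    path = Path(path)
    sid = subject_id if subject_id is not None else path.stem
    if dialect == "square_csv":
        # round_trip parsing: repr-precision weights must reload bit-exact
        frame = pd.read_csv(path, header=0, float_precision="round_trip")
        labels = tuple(str(c) for c in frame.columns)
        return ConnectivityMatrix(
            subject_id=sid, weights=frame.to_numpy(dtype=float), roi_labels=labels
        )
    if dialect == "edge_list":
        if roi_labels is None:
            raise ValueError("edge_list dialect requires roi_labels")
        labels = tuple(str(r) for r in roi_labels)
        pos = {lab: i for i, lab in enumerate(labels)}
        w = np.zeros((len(labels), len(labels)))
        seen: set[tuple[int, int]] = set()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                parts = line.split()
                if not parts or parts[0].startswith("#"):
                    continue
                if len(parts) != 3:
                    raise ConnectomeValidationError(
                        f"{path}:{lineno}: expected 'roi_a roi_b weight', got {line!r}"
                    )
                a, b, weight = parts
                for roi in (a, b):
                    if roi not in pos:
                        raise ConnectomeValidationError(
                            f"{path}:{lineno}: unknown ROI label {roi!r}"
                        )
                i, j = pos[a], pos[b]
                key = (min(i, j), max(i, j))
                if key in seen:
                    raise ConnectomeValidationError(
                        f"{path}:{lineno}: duplicate edge ({a}, {b})"
                    )
                seen.add(key)
                w[i, j] = w[j, i] = float(weight)
        return ConnectivityMatrix(subject_id=sid, weights=w, roi_labels=labels)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_matrix(
    matrix: ConnectivityMatrix,
    path: str | Path,
    dialect: Literal["square_csv", "edge_list"] = "square_csv",
) -> None:
    """Write a connectivity matrix in one of the supported text dialects.

    ``edge_list`` output contains only nonzero edges, ``repr``-precision
    floats so a round trip reproduces the weights exactly.
    """
    path = Path(path)
    if dialect == "square_csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(matrix.roi_labels)
            for row in matrix.weights:
                writer.writerow([repr(float(x)) for x in row])
    elif dialect == "edge_list":
        iu, ju = np.triu_indices(matrix.n_rois, k=1)
        with open(path, "w") as fh:
            for i, j in zip(iu, ju):
                w = float(matrix.weights[i, j])
                if w != 0:
                    fh.write(f"{matrix.roi_labels[i]}\t{matrix.roi_labels[j]}\t{w!r}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_cohort_table(path: str | Path, required: Iterable[str] = ("age",)) -> pd.DataFrame:
    """Load the cohort metadata CSV and validate it.

    The table must contain ``subject_id`` and ``sex`` columns; ``required``
    names the attribute columns that must be present and complete (subjects
    with missing values in an analyzed attribute are a hard error — they
    should be excluded upstream, mirroring the exclusion of incomplete
    subjects from the study cohort).
    """
    table = pd.read_csv(path, dtype={"subject_id": str})
    return validate_cohort_table(table, required=required)


def validate_cohort_table(
    table: pd.DataFrame, required: Iterable[str] = ("age",)
) -> pd.DataFrame:
    table = table.copy()
    if "subject_id" not in table.columns or "sex" not in table.columns:
        raise ConnectomeValidationError("cohort table needs 'subject_id' and 'sex' columns")
    table["subject_id"] = table["subject_id"].astype(str)
    if table["subject_id"].duplicated().any():
        dupes = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise ConnectomeValidationError(f"duplicate subject ids: {dupes}")
    bad_sex = set(table["sex"].unique()) - {"male", "female"}
    if bad_sex:
        raise ConnectomeValidationError(f"sex must be 'male'/'female', got {sorted(bad_sex)}")
    for col in required:
        if col not in table.columns:
            raise ConnectomeValidationError(f"missing required attribute column {col!r}")
        if table[col].isna().any():
            n_missing = int(table[col].isna().sum())
            raise ConnectomeValidationError(
                f"attribute {col!r} has {n_missing} missing values; "
                "exclude incomplete subjects before analysis"
            )
    return table


def assemble_design_matrix(
    matrices: Iterable[ConnectivityMatrix], cohort: pd.DataFrame
) -> DesignMatrix:
    """Stack vectorized matrices into the design matrix ``A`` in cohort order.

    Every cohort subject must have exactly one matrix; all matrices must
    share ROI labels and order.  The iteration order of ``matrices`` is
    irrelevant — row order is governed by the cohort table.
    """
    by_id: dict[str, ConnectivityMatrix] = {}
    for mat in matrices:
        if mat.subject_id in by_id:
            raise ConnectomeValidationError(f"duplicate matrix for subject {mat.subject_id!r}")
        by_id[mat.subject_id] = mat
    wanted = [str(s) for s in cohort["subject_id"]]
    missing = [s for s in wanted if s not in by_id]
    if missing:
        raise ConnectomeValidationError(f"no connectivity matrix for subjects: {missing}")
    ref = by_id[wanted[0]]
    for sid in wanted[1:]:
        if by_id[sid].roi_labels != ref.roi_labels:
            raise ConnectomeValidationError(
                f"ROI labels of subject {sid!r} differ from {ref.subject_id!r}"
            )
    rows = np.stack([vectorize(by_id[sid]) for sid in wanted])
    return DesignMatrix(
        values=rows,
        edge_index=edge_index_for(ref.roi_labels),
        subject_order=tuple(wanted),
    )
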