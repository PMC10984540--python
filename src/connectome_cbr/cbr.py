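"""Correlation-based regression (CBR) on vectorized connectomes.

Given the n x m design matrix ``A`` (subjects x edges) and an attribute
vector ``b`` of length n, the model is:

1. the correlation vector ``R`` of length m, ``R_i = r(A_i, b)`` — the
   sample Pearson correlation of edge column i with the attribute;
2. the per-subject predictor score ``S_j = sum_x A[j, x] * R[x]`` — each
   subject's connection strengths summed, weighted by the edge's
   correlation coefficient (the scalar product of subject row j with R);
3. a simple linear least-squares calibration of the attribute on the score,
   ``b ~ slope * S + intercept``, used to predict held-out subjects.

All m edges contribute, signed; there is no thresholding or selection
(unlike classical connectome-based predictive modeling, which keeps only
edges past a p-value cutoff).  Edge columns with zero variance have no
defined correlation; they are assigned R = 0 — equivalent to excluding
them from the weighted sum — and recorded.

Because Pearson correlation is invariant to positive rescaling and shifts
of the edge weights and the OLS calibration absorbs the scale and offset of
S, predictions are invariant under a global positive rescaling of all
connectivity data and under adding a constant to any edge column.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import DesignMatrix

logger = logging.getLogger(__name__)


class DegenerateAttributeError(ValueError):
    """The attribute vector has zero variance; correlations are undefined."""


@dataclass
class EdgeCorrelationVector:
    """Per-edge Pearson correlations with an attribute (the vector ``R``)."""

    values: np.ndarray
    attribute_name: str
    n_train: int
    zero_variance_edges: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (np.nanmax(np.abs(self.values)) > 1.0 + 1e-12):
            raise ValueError("correlation entries must lie in [-1, 1]")


@dataclass
class PredictorScores:
    """Per-subject correlation-weighted sums ``S`` (scale-covariant units)."""

    values: np.ndarray
    subject_order: tuple[str, ...]


@dataclass
class FittedCbrModel:
    """A correlation vector plus linear calibration learned on training data.

    ``slope`` is in attribute units per score unit, ``intercept`` in
    attribute units.  ``edge_index`` persists the edge ordering so that
    predictions are well-defined across files.
    """

    correlations: EdgeCorrelationVector
    slope: float
    intercept: float
    edge_index: tuple[tuple[str, str], ...]
    training_subject_ids: frozenset[str]
    degenerate: bool = False


def _attribute_vector(b) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    if b.ndim != 1:
        raise ValueError("attribute vector must be one-dimensional")
    return b


def edge_attribute_correlations(
    A_train: DesignMatrix, b_train, attribute_name: str = ""
) -> EdgeCorrelationVector:
    """Compute ``R``: the Pearson correlation of every edge with the attribute.

    Columns with zero variance get correlation 0 and are recorded in
    ``zero_variance_edges``.

    Raises
    ------
    DegenerateAttributeError
        If ``b_train`` is constant (every correlation undefined).
    ValueError
        If fewer than 3 training subjects or misaligned shapes.
    """
    b = _attribute_vector(b_train)
    A = A_train.values
    if A.shape[0] != b.shape[0]:
        raise ValueError(
            f"design matrix has {A.shape[0]} rows but attribute vector length {b.shape[0]}"
        )
    if A.shape[0] < 3:
        raise ValueError("need at least 3 training subjects for correlations")
    bc = b - b.mean()
    b_ss = float(bc @ bc)
    if b_ss == 0.0:
        raise DegenerateAttributeError("attribute has zero variance")
    Ac = A - A.mean(axis=0)
    col_ss = np.einsum("ij,ij->j", Ac, Ac)
    zero_var = col_ss == 0.0
    denom = np.sqrt(col_ss * b_ss)
    denom[zero_var] = 1.0  # placeholder; numerator is 0 there too
    r = (Ac.T @ bc) / denom
    r[zero_var] = 0.0
    # guard against roundoff pushing |r| infinitesimally past 1
    np.clip(r, -1.0, 1.0, out=r)
    return EdgeCorrelationVector(
        values=r,
        attribute_name=attribute_name,
        n_train=A.shape[0],
        zero_variance_edges=frozenset(int(i) for i in np.nonzero(zero_var)[0]),
    )


def predictor_scores(A: DesignMatrix, R: EdgeCorrelationVector) -> PredictorScores:
    """Compute ``S``: each subject row's scalar product with ``R``."""
    if A.values.shape[1] != R.values.shape[0]:
        raise ValueError(
            f"edge-count mismatch: design matrix has {A.values.shape[1]} edges, "
            f"correlation vector {R.values.shape[0]}"
        )
    return PredictorScores(values=A.values @ R.values, subject_order=A.subject_order)


def fit_cbr(
    A_train: DesignMatrix, b_train, attribute_name: str = ""
) -> FittedCbrModel:
    """Fit the full CBR model on training data only.

    Computes R on the training set, the training scores S, then ordinary
    least squares of the attribute on S (one slope, one intercept).  If the
    training scores are constant (e.g. R identically zero) the model
    degenerates to predicting the training mean, with a logged warning.
    """
    b = _attribute_vector(b_train)
    R = edge_attribute_correlations(A_train, b, attribute_name)
    S = predictor_scores(A_train, R).values
    Sc = S - S.mean()
    s_ss = float(Sc @ Sc)
    if s_ss == 0.0:
        logger.warning(
            "constant predictor scores for attribute %r: degenerate model "
            "(slope 0, intercept = training mean)",
            attribute_name,
        )
        slope, intercept, degenerate = 0.0, float(b.mean()), True
    else:
        slope = float(Sc @ (b - b.mean())) / s_ss
        intercept = float(b.mean() - slope * S.mean())
        degenerate = False
    return FittedCbrModel(
        correlations=R,
        slope=slope,
        intercept=intercept,
        edge_index=A_train.edge_index,
        training_subject_ids=frozenset(A_train.subject_order),
        degenerate=degenerate,
    )


def predict(model: FittedCbrModel, A_new: DesignMatrix) -> np.ndarray:
    """Predict the attribute for new subjects from quantities frozen at fit time."""
    if A_new.edge_index != model.edge_index:
        if len(A_new.edge_index) != len(model.edge_index):
            raise ValueError(
                f"edge-count mismatch: model has {len(model.edge_index)} edges, "
                f"input {len(A_new.edge_index)}"
            )
        raise ValueError("edge ordering of input differs from the fitted model")
    S = A_new.values @ model.correlations.values
    return model.intercept + model.slope * S


def extreme_correlations(R: EdgeCorrelationVector) -> tuple[float, float]:
    """Minimum and maximum entries of R, excluding zero-variance placeholders.

    Reported per dataset on the full data (not a CV fold) to summarize how
    strongly any single edge tracks the attribute.
    """
    vals = R.values
    if R.zero_variance_edges:
        keep = np.ones(vals.shape[0], dtype=bool)
        keep[list(R.zero_variance_edges)] = False
        vals = vals[keep]
    if vals.size == 0:
        raise ValueError("no defined correlations: all edges have zero variance")
    return float(vals.min()), float(vals.max())


def save_model(model: FittedCbrModel, path: str | Path) -> None:
    """Persist a fitted model as a self-describing JSON artifact."""
    payload = {
        "format": "connectome-cbr-model",
        "version": 1,
        "attribute_name": model.correlations.attribute_name,
        "n_train": model.correlations.n_train,
        "slope": model.slope,
        "intercept": model.intercept,
        "degenerate": model.degenerate,
        "edge_index": [list(e) for e in model.edge_index],
        "correlations": model.correlations.values.tolist(),
        "zero_variance_edges": sorted(model.correlations.zero_variance_edges),
        "training_subject_ids": sorted(model.training_subject_ids),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> FittedCbrModel:
    """Load a model saved by :func:`save_model`; reproduces predictions exactly."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "connectome-cbr-model":
        raise ValueError(f"{path}: not a connectome-cbr model file")
    R = EdgeCorrelationVector(
        values=np.asarray(payload["correlations"], dtype=float),
        attribute_name=payload["attribute_name"],
        n_train=int(payload["n_train"]),
        zero_variance_edges=frozenset(payload["zero_variance_edges"]),
    )
    return FittedCbrModel(
        correlations=R,
        slope=float(payload["slope"]),
        intercept=float(payload["intercept"]),
        edge_index=tuple((a, b) for a, b in payload["edge_index"]),
        training_subject_ids=frozenset(payload["training_subject_ids"]),
        degenerate=bool(payload["degenerate"]),
    )
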