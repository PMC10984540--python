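"""Leakage-safe cross-validated evaluation of the CBR model.

A 10-fold cross-validation refits the *entire* model — edge-attribute
correlation vector and the linear calibration — on the out-of-fold
subjects for every fold, then predicts the in-fold subjects, so no
test-fold information can leak into fitting.  Every subject is predicted
exactly once; metrics are pooled over all subjects across folds:

* Pearson r between predicted and actual values, with the nominal
  two-sided p-value from the t distribution on n - 2 degrees of freedom;
* MAE, the mean of per-subject absolute errors, with its sample standard
  deviation;
* NMAE, the MAE divided by the range (max - min) of the *actual* values of
  the evaluated group — using the group's own observed range makes
  subgroup NMAEs directly comparable across datasets of different spread.

Pooling (one r, one MAE over all n subjects) rather than per-fold
averaging is what the paired-error statistics require: each subject
contributes exactly one absolute error.  A per-fold-averaged variant is
exposed as :func:`per_fold_metrics` for comparison.

Sex-specific results come from an *independent* cross-validation inside
the subgroup (refit, not a post-hoc slice of the full-cohort run); the
slicing variant is available via ``slice_cv_result``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cbr import fit_cbr, predict
from .io import DesignMatrix


@dataclass(frozen=True)
class FoldAssignment:
    """A seeded partition of subjects into k folds of near-equal size."""

    k: int
    assignment: dict[str, int]
    seed: int

    def test_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.assignment.items() if f == fold]

    def train_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.assignment.items() if f != fold]


@dataclass
class CvResult:
    """Per-subject cross-validation records.

    ``records`` columns: subject_id, fold, actual, predicted,
    absolute_error (all in attribute units).  One record per subject, in
    cohort order.
    """

    records: pd.DataFrame
    attribute_name: str
    dataset_label: str = ""
    subgroup: Literal["all", "male", "female"] = "all"

    def absolute_errors(self) -> pd.Series:
        """Per-subject absolute errors indexed by subject_id."""
        return self.records.set_index("subject_id")["absolute_error"]


@dataclass(frozen=True)
class MetricsReport:
    """Pooled prediction-quality metrics for one CV run."""

    pearson_r: float
    pearson_p: float
    mae: float
    mae_sd: float
    nmae: float
    n: int
    range_used: float


def kfold_split(subject_ids: Sequence[str], k: int, seed: int) -> FoldAssignment:
    """Partition subjects into k folds by a seeded uniform permutation.

    The shuffled order is cut into k contiguous blocks whose sizes differ
    by at most one (the first ``n mod k`` folds get the extra subject).
    No stratification by attribute or sex is applied.
    """
    ids = [str(s) for s in subject_ids]
    n = len(ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of subjects ({n})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment: dict[str, int] = {}
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    start = 0
    for fold, size in enumerate(sizes):
        for idx in perm[start : start + size]:
            assignment[ids[idx]] = fold
        start += size
    return FoldAssignment(k=k, assignment=assignment, seed=seed)


def cross_validate(
    A: DesignMatrix,
    cohort: pd.DataFrame,
    attribute: str,
    folds: FoldAssignment,
    dataset_label: str = "",
    subgroup: Literal["all", "male", "female"] = "all",
) -> CvResult:
    """Run the leakage-safe cross-validation for one attribute.

    For each fold the CBR model (correlations *and* calibration) is fitted
    on the out-of-fold subjects only and used to predict the in-fold
    subjects.  Raises if a training fold has a constant attribute (the
    split is degenerate) or the fold assignment does not cover the cohort.
    """
    if attribute not in cohort.columns:
        raise KeyError(f"attribute {attribute!r} not in cohort table")
    if cohort[attribute].isna().any():
        raise ValueError(f"attribute {attribute!r} has missing values")
    ids = [str(s) for s in cohort["subject_id"]]
    if list(A.subject_order) != ids:
        raise ValueError("design matrix subject order does not match cohort table")
    missing = [s for s in ids if s not in folds.assignment]
    if missing:
        raise ValueError(f"subjects without fold assignment: {missing}")
    b = cohort[attribute].to_numpy(dtype=float)
    pos = {s: i for i, s in enumerate(ids)}
    fold_of = np.array([folds.assignment[s] for s in ids])
    predicted = np.full(len(ids), np.nan)
    for fold in range(folds.k):
        train = fold_of != fold
        test = ~train
        if not test.any():
            continue
        b_tr = b[train]
        if np.ptp(b_tr) == 0:
            raise ValueError(
                f"degenerate split: training attribute constant when holding out fold {fold}"
            )
        A_tr = DesignMatrix(
            values=A.values[train],
            edge_index=A.edge_index,
            subject_order=tuple(np.array(ids)[train]),
        )
        model = fit_cbr(A_tr, b_tr, attribute)
        A_te = DesignMatrix(
            values=A.values[test],
            edge_index=A.edge_index,
            subject_order=tuple(np.array(ids)[test]),
        )
        predicted[test] = predict(model, A_te)
    records = pd.DataFrame(
        {
            "subject_id": ids,
            "fold": fold_of,
            "actual": b,
            "predicted": predicted,
            "absolute_error": np.abs(predicted - b),
        }
    )
    return CvResult(
        records=records,
        attribute_name=attribute,
        dataset_label=dataset_label,
        subgroup=subgroup,
    )


def compute_metrics(cv: CvResult) -> MetricsReport:
    """Pooled metrics over all folds of a CV run.

    MAE is the mean absolute error over subjects, with its sample standard
    deviation; NMAE divides by the observed range of actual values; the
    Pearson r/p are computed on the pooled predicted-vs-actual pairs.
    """
    rec = cv.records
    if rec.empty:
        raise ValueError("empty CV result")
    n = len(rec)
    if n < 3:
        raise ValueError("need at least 3 subjects for a p-value (n - 2 dof)")
    actual = rec["actual"].to_numpy(dtype=float)
    predicted = rec["predicted"].to_numpy(dtype=float)
    rng_used = float(actual.max() - actual.min())
    if rng_used == 0:
        raise ValueError("actual values are constant: NMAE undefined")
    abs_err = np.abs(predicted - actual)
    mae = float(abs_err.mean())
    mae_sd = float(abs_err.std(ddof=1))
    if np.ptp(predicted) == 0:
        r, p = 0.0, 1.0  # degenerate predictor: correlation undefined, report null
    else:
        r, p = stats.pearsonr(predicted, actual)
    return MetricsReport(
        pearson_r=float(r),
        pearson_p=float(p),
        mae=mae,
        mae_sd=mae_sd,
        nmae=mae / rng_used,
        n=n,
        range_used=rng_used,
    )


def per_fold_metrics(cv: CvResult) -> pd.DataFrame:
    """Per-fold r/MAE (the averaging alternative to pooling), for comparison."""
    rows = []
    for fold, grp in cv.records.groupby("fold"):
        err = grp["absolute_error"].to_numpy()
        if len(grp) >= 3 and np.ptp(grp["predicted"].to_numpy()) > 0:
            r = float(stats.pearsonr(grp["predicted"], grp["actual"])[0])
        else:
            r = np.nan
        rows.append({"fold": int(fold), "n": len(grp), "mae": float(err.mean()), "r": r})
    return pd.DataFrame(rows)


def subgroup_metrics(
    A: DesignMatrix,
    cohort: pd.DataFrame,
    attribute: str,
    sex: Literal["all", "male", "female"],
    k: int,
    seed: int,
    dataset_label: str = "",
) -> tuple[CvResult, MetricsReport]:
    """Independent cross-validation restricted to one sex subgroup.

    The model is refitted inside the subgroup and the NMAE denominator is
    the subgroup's own observed range of actual values.  ``sex="all"``
    degenerates to a plain full-cohort run.
    """
    if sex == "all":
        keep = np.ones(len(cohort), dtype=bool)
    else:
        keep = (cohort["sex"] == sex).to_numpy()
    n_sub = int(keep.sum())
    if n_sub < k:
        raise ValueError(f"subgroup {sex!r} has {n_sub} subjects, fewer than k = {k}")
    sub_cohort = cohort.loc[keep].reset_index(drop=True)
    sub_A = DesignMatrix(
        values=A.values[keep],
        edge_index=A.edge_index,
        subject_order=tuple(np.array(A.subject_order)[keep]),
    )
    folds = kfold_split(sub_cohort["subject_id"], k=k, seed=seed)
    cv = cross_validate(
        sub_A, sub_cohort, attribute, folds, dataset_label=dataset_label, subgroup=sex
    )
    return cv, compute_metrics(cv)


def slice_cv_result(cv: CvResult, cohort: pd.DataFrame, sex: str) -> CvResult:
    """Post-hoc slice of a full-cohort CV by sex (no refit); the alternative
    reading of subgroup analysis, kept available for comparison."""
    ids = set(cohort.loc[cohort["sex"] == sex, "subject_id"].astype(str))
    records = cv.records[cv.records["subject_id"].isin(ids)].reset_index(drop=True)
    return CvResult(
        records=records,
        attribute_name=cv.attribute_name,
        dataset_label=cv.dataset_label,
        subgroup=sex,  # type: ignore[arg-type]
    )
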