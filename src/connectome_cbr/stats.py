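"""Paired-error statistics: Wilcoxon signed-rank tests with BH-FDR control.

Model comparison works on the per-subject absolute errors produced by
cross-validation: two conditions (datasets/parcellations, or two
attributes with a shared scale) are compared by a two-sided Wilcoxon
signed-rank test on the paired error differences, and each family of
comparisons is corrected with the Benjamini-Hochberg step-up procedure at
FDR q = 0.05.

Conventions (deterministic, documented):

* zero differences are discarded before ranking (Wilcoxon's original
  convention); the effective n after removal is reported;
* the exact null distribution is used for effective n <= 25 when there are
  no ties among the absolute differences; otherwise the normal
  approximation with tie correction and continuity correction;
* all-zero differences give p = 1 with a degeneracy flag instead of an
  error, so degenerate self-comparisons stay representable in a family.

One BH family is formed per (attribute, subgroup), containing all pairwise
dataset comparisons for that attribute.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .evaluation import CvResult

#: effective-n threshold below which the exact signed-rank null is used
EXACT_N_MAX = 25


@dataclass
class PairedComparison:
    """One two-sided signed-rank test between two error conditions."""

    label_a: str
    label_b: str
    differences: np.ndarray  # errors_a - errors_b, per subject, zeros included
    statistic: float  # signed: W+ - W- over the nonzero differences
    p_value: float
    n_effective: int
    method: str  # "exact" | "approx" | "degenerate"

    @property
    def degenerate(self) -> bool:
        return self.method == "degenerate"

    @property
    def median_difference(self) -> float:
        return float(np.median(self.differences))


@dataclass
class FdrFamily:
    """A family of comparisons corrected together by Benjamini-Hochberg."""

    comparisons: list[PairedComparison]
    fdr_q: float
    adjusted_p: np.ndarray
    rejected: np.ndarray
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition_a": [c.label_a for c in self.comparisons],
                "condition_b": [c.label_b for c in self.comparisons],
                "n_effective": [c.n_effective for c in self.comparisons],
                "statistic": [c.statistic for c in self.comparisons],
                "raw_p": [c.p_value for c in self.comparisons],
                "adjusted_p": self.adjusted_p,
                "rejected": self.rejected,
            }
        )


def _align_errors(errors_a, errors_b) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(errors_a, pd.Series) and isinstance(errors_b, pd.Series):
        if set(errors_a.index) != set(errors_b.index):
            raise ValueError("subject sets differ between the two error conditions")
        errors_b = errors_b.reindex(errors_a.index)
        return errors_a.to_numpy(dtype=float), errors_b.to_numpy(dtype=float)
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired error vectors must have identical length")
    return a, b


def paired_wilcoxon(
    errors_a, errors_b, label_a: str = "a", label_b: str = "b"
) -> PairedComparison:
    """Two-sided Wilcoxon signed-rank test on paired absolute errors.

    ``errors_a``/``errors_b`` are per-subject absolute errors; pandas
    Series are aligned on their (subject-id) index, arrays positionally.
    Requires n >= 5 after zero-difference removal unless every difference
    is zero (degenerate, p = 1).
    """
    a, b = _align_errors(errors_a, errors_b)
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        return PairedComparison(
            label_a=label_a, label_b=label_b, differences=d,
            statistic=0.0, p_value=1.0, n_effective=0, method="degenerate",
        )
    if nz.size < 5:
        raise ValueError(
            f"only {nz.size} nonzero paired differences; need >= 5 for the test"
        )
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= EXACT_N_MAX and not has_ties) else "approx"
    res = stats.wilcoxon(
        nz,
        zero_method="wilcox",
        correction=(method == "approx"),
        alternative="two-sided",
        method=method,
    )
    # scipy reports W+ (rank sum of positive differences); signed statistic
    # W+ - W- makes the direction visible and antisymmetric under swap
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    w_minus = float(ranks[nz < 0].sum())
    return PairedComparison(
        label_a=label_a, label_b=label_b, differences=d,
        statistic=w_plus - w_minus, p_value=float(min(res.pvalue, 1.0)),
        n_effective=int(nz.size), method=method,
    )


def benjamini_hochberg(p_values: Sequence[float], q: float = 0.05):
    """Benjamini-Hochberg step-up decisions for a family of p-values.

    Returns ``(rejected, adjusted_p)`` arrays in the input order.  The
    step-up procedure sorts ascending, finds the largest i with
    ``p(i) <= i*q/m`` and rejects hypotheses 1..i; adjusted p-values are
    the monotone ``min_{j>=i} m*p(j)/j`` capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return rejected, adjusted


def _family(
    comparisons: list[PairedComparison], q: float, label: str = ""
) -> FdrFamily:
    rejected, adjusted = benjamini_hochberg([c.p_value for c in comparisons], q=q)
    return FdrFamily(
        comparisons=comparisons, fdr_q=q,
        adjusted_p=adjusted, rejected=rejected, label=label,
    )


def compare_across_conditions(
    results: Sequence[CvResult], family_label: str = "", q: float = 0.05
) -> FdrFamily:
    """All pairwise dataset comparisons for one attribute, BH-corrected.

    Every CvResult must share the attribute and the subject set (paired
    design).  With c conditions the family holds C(c, 2) comparisons —
    e.g. 6 parcellation conditions give 15 tests.
    """
    if len(results) < 2:
        raise ValueError("need at least two conditions to compare")
    attrs = {r.attribute_name for r in results}
    if len(attrs) != 1:
        raise ValueError(f"conditions mix attributes: {sorted(attrs)}")
    ref_ids = set(results[0].records["subject_id"])
    for r in results[1:]:
        if set(r.records["subject_id"]) != ref_ids:
            raise ValueError(
                f"subject sets differ between {results[0].dataset_label!r} "
                f"and {r.dataset_label!r}"
            )
    comparisons = [
        paired_wilcoxon(
            ra.absolute_errors(), rb.absolute_errors(),
            label_a=ra.dataset_label or f"cond{ia}",
            label_b=rb.dataset_label or f"cond{ib}",
        )
        for (ia, ra), (ib, rb) in itertools.combinations(enumerate(results), 2)
    ]
    return _family(comparisons, q=q, label=family_label)


def compare_feature_pair(cv_a: CvResult, cv_b: CvResult) -> PairedComparison:
    """Paired test between two attributes' errors within one dataset.

    Only meaningful when the two attributes share units and range (e.g.
    fluid vs crystallized intelligence composite scores, which are on the
    same scale) — the caller vouches for that comparability.
    """
    return paired_wilcoxon(
        cv_a.absolute_errors(), cv_b.absolute_errors(),
        label_a=f"{cv_a.dataset_label}:{cv_a.attribute_name}",
        label_b=f"{cv_b.dataset_label}:{cv_b.attribute_name}",
    )


def feature_pair_family(
    pairs: Sequence[tuple[CvResult, CvResult]], q: float = 0.05, label: str = ""
) -> FdrFamily:
    """BH family over per-dataset attribute-pair comparisons (one per dataset)."""
    comparisons = [compare_feature_pair(a, b) for a, b in pairs]
    return _family(comparisons, q=q, label=label)
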