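"""Synthetic connectome cohorts with known ground truth.

The study cohorts this generator emulates are structural-connectome
datasets (HCP young adults, ADNI-3 elderly controls): per subject a square
symmetric nonnegative matrix of streamline-count-like edge weights, plus
demographic attributes (age, NIH-Toolbox intelligence composite scores).
No public generative model exists for such data, so the generator states
the simplest mechanism that yields nonnegative right-skewed weights with an
exactly controllable population edge-attribute correlation:

* attributes are truncated normals (rejection-sampled so the moments stay
  interpretable) with the cohorts' published min/max/mean/sd;
* background edges sit on a fixed random mask at ``edge_density`` and carry
  i.i.d. log-normal weights, independent of every attribute;
* each *signal* edge is linear in its attribute plus Gaussian noise,
  ``w = offset + beta * (b - mean(b)) + eps`` with ``eps ~ N(0, noise_sd^2)``
  and ``beta = rho * noise_sd / (sigma_b * sqrt(1 - rho^2))``, so the
  population correlation with the attribute is exactly ``planted_rho``
  whatever the noise scale; the default ``noise_sd`` matches
  ``base_weight_scale`` so planted edges disperse like background edges;
  the offset sits 4 total-sd above zero, keeping clipping in the far tail;
* negative weights (possible after noise) are clipped to zero; if clipping
  distorts a planted correlation by more than 10% of its analytic value a
  warning is recorded in the ground-truth manifest rather than silently
  resampled.

Everything is a deterministic function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    ConnectivityMatrix,
    DesignMatrix,
    edge_index_for,
    write_matrix,
)

#: shape parameter of the log-normal background weights (right skew akin to
#: streamline counts; the median is ``base_weight_scale``)
LOGNORMAL_SIGMA = 1.0

#: relative correlation distortion beyond which clipping is flagged
CLIP_WARNING_FRACTION = 0.10


class SpecValidationError(ValueError):
    """A CohortSpec field violates its contract; the message names the field."""


@dataclass(frozen=True)
class AttributeSpec:
    """Distribution of one subject attribute: truncated normal on [min, max]."""

    name: str
    mean: float
    sd: float
    minimum: float
    maximum: float

    def validate(self) -> None:
        if self.minimum >= self.maximum:
            raise SpecValidationError(
                f"attribute {self.name!r}: min ({self.minimum}) must be < max ({self.maximum})"
            )
        if not (self.minimum <= self.mean <= self.maximum):
            raise SpecValidationError(
                f"attribute {self.name!r}: mean ({self.mean}) outside [min, max]"
            )
        if self.sd < 0:
            raise SpecValidationError(f"attribute {self.name!r}: sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort.

    ``n_signal_edges`` and ``planted_rho`` may be a single value (applied to
    every attribute) or a mapping keyed by attribute name.  ``planted_rho``
    is the target *population* Pearson correlation between each signal
    edge's weight and its attribute, in (-1, 1).
    """

    n_subjects: int
    n_rois: int
    attribute_specs: tuple[AttributeSpec, ...]
    sex_fraction_female: float = 0.5
    n_signal_edges: int | Mapping[str, int] = 0
    planted_rho: float | Mapping[str, float] = 0.0
    noise_sd: float = 100.0
    edge_density: float = 0.3
    base_weight_scale: float = 100.0
    seed: int = 0

    @property
    def n_edges(self) -> int:
        return self.n_rois * (self.n_rois - 1) // 2

    @property
    def attribute_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.attribute_specs)

    def signal_edges_for(self, name: str) -> int:
        if isinstance(self.n_signal_edges, Mapping):
            return int(self.n_signal_edges.get(name, 0))
        return int(self.n_signal_edges)

    def rho_for(self, name: str) -> float:
        if isinstance(self.planted_rho, Mapping):
            return float(self.planted_rho.get(name, 0.0))
        return float(self.planted_rho)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise SpecValidationError("n_subjects must be a positive integer")
        if self.n_rois < 2:
            raise SpecValidationError("n_rois must be >= 2")
        if not self.attribute_specs:
            raise SpecValidationError("attribute_specs must be non-empty")
        names = self.attribute_names
        if len(set(names)) != len(names):
            raise SpecValidationError("attribute_specs: duplicate attribute names")
        for a in self.attribute_specs:
            a.validate()
        if not (0.0 <= self.sex_fraction_female <= 1.0):
            raise SpecValidationError("sex_fraction_female must be in [0, 1]")
        total_signal = 0
        for name in names:
            k = self.signal_edges_for(name)
            rho = self.rho_for(name)
            if k < 0:
                raise SpecValidationError(f"n_signal_edges for {name!r} must be >= 0")
            if not (-1.0 < rho < 1.0):
                raise SpecValidationError(f"planted_rho for {name!r} must satisfy |rho| < 1")
            if k > 0 and rho != 0.0 and self.noise_sd <= 0:
                raise SpecValidationError(
                    "noise_sd must be > 0 when planting a nonzero correlation"
                )
            total_signal += k
        if total_signal > self.n_edges:
            raise SpecValidationError(
                f"n_signal_edges total ({total_signal}) exceeds edge count "
                f"{self.n_edges} = n_rois*(n_rois-1)/2"
            )
        if not (0.0 < self.edge_density <= 1.0):
            raise SpecValidationError("edge_density must be in (0, 1]")
        if self.base_weight_scale <= 0:
            raise SpecValidationError("base_weight_scale must be > 0")
        if self.noise_sd < 0:
            raise SpecValidationError("noise_sd must be >= 0")


# ----------------------------------------------------------------------------
# published cohort descriptors (age in years; intelligence in NIH-Toolbox
# composite-score units)

HCP_ATTRIBUTES = (
    AttributeSpec("age", mean=28.75, sd=3.68, minimum=22.0, maximum=37.0),
    AttributeSpec("intel_total", mean=122.26, sd=14.46, minimum=88.50, maximum=153.36),
    AttributeSpec("intel_fluid", mean=115.39, sd=11.54, minimum=86.68, maximum=145.17),
    AttributeSpec("intel_cryst", mean=117.92, sd=9.81, minimum=90.95, maximum=153.95),
)

ADNI_ATTRIBUTES = (
    AttributeSpec("age", mean=74.43, sd=7.86, minimum=56.5, maximum=91.5),
)


def hcp_like_spec(n_subjects: int = 1048, n_rois: int = 40, **overrides) -> CohortSpec:
    """A spec with the HCP young-adult cohort's attribute distributions.

    Defaults: 1048 subjects (484 male, 564 female -> female fraction
    564/1048), age 22-37 (mean 28.75, sd 3.68) and the three intelligence
    composites.  ``n_rois`` defaults to a desk-scale 40 (the real pipeline
    used 379 ROIs, i.e. 71 631 edges).
    """
    spec = CohortSpec(
        n_subjects=n_subjects,
        n_rois=n_rois,
        attribute_specs=HCP_ATTRIBUTES,
        sex_fraction_female=564 / 1048,
    )
    return replace(spec, **overrides) if overrides else spec


def adni_like_spec(n_subjects: int = 94, n_rois: int = 40, **overrides) -> CohortSpec:
    """A spec with the ADNI-3 control cohort's age distribution.

    Defaults: 94 subjects (40 male, 54 female), age 56.5-91.5 (mean 74.43,
    sd 7.86).
    """
    spec = CohortSpec(
        n_subjects=n_subjects,
        n_rois=n_rois,
        attribute_specs=ADNI_ATTRIBUTES,
        sex_fraction_female=54 / 94,
    )
    return replace(spec, **overrides) if overrides else spec


# ----------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    """A generated cohort: matrices, metadata, and the ground-truth manifest.

    ``ground_truth`` has one row per (attribute, signal edge):
    ``attribute, edge_index, roi_a, roi_b, planted_rho, realized_r,
    clip_warning``.  ``realized_r`` is the sample correlation of the final
    (clipped) edge weight with the attribute; ``clip_warning`` is True when
    clipping moved it more than 10% of the analytic value.
    """

    spec: CohortSpec
    matrices: list[ConnectivityMatrix]
    cohort_table: pd.DataFrame
    ground_truth: pd.DataFrame
    seed_used: int
    roi_labels: tuple[str, ...]
    _edge_values: np.ndarray = field(repr=False, default=None)

    def design_matrix(self) -> DesignMatrix:
        """The n x m design matrix ``A`` of vectorized connectomes."""
        return DesignMatrix(
            values=self._edge_values.copy(),
            edge_index=edge_index_for(self.roi_labels),
            subject_order=tuple(self.cohort_table["subject_id"]),
        )

    def signal_edge_positions(self, attribute: str) -> np.ndarray:
        gt = self.ground_truth
        return gt.loc[gt["attribute"] == attribute, "edge_index"].to_numpy(dtype=int)


def _truncated_normal(
    rng: np.random.Generator, spec: AttributeSpec, size: int
) -> np.ndarray:
    """Rejection-sample N(mean, sd) truncated to [min, max]."""
    if spec.sd == 0:
        return np.full(size, spec.mean)
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(spec.mean, spec.sd, size=2 * (size - filled) + 16)
        keep = draw[(draw >= spec.minimum) & (draw <= spec.maximum)]
        take = min(len(keep), size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def generate_attributes(spec: CohortSpec) -> pd.DataFrame:
    """Generate the cohort metadata table for a spec.

    One row per subject: ``subject_id``, ``sex`` (independent draws at
    ``sex_fraction_female``), and one column per attribute drawn from its
    truncated normal.  Deterministic in ``spec.seed``.
    """
    spec.validate()
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(0,))
    rng = np.random.default_rng(ss)
    n = spec.n_subjects
    width = max(4, len(str(n)))
    table = {
        "subject_id": [f"S{i:0{width}d}" for i in range(n)],
        "sex": np.where(rng.random(n) < spec.sex_fraction_female, "female", "male"),
    }
    for a in spec.attribute_specs:
        table[a.name] = _truncated_normal(rng, a, n)
    return pd.DataFrame(table)


def _sample_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    return float((xc * yc).sum() / denom) if denom > 0 else 0.0


def generate_connectomes(spec: CohortSpec, cohort: pd.DataFrame) -> SyntheticCohort:
    """Generate per-subject connectivity matrices with planted signal.

    ``cohort`` must come from :func:`generate_attributes` with the same
    spec.  Signal edges are drawn uniformly (without replacement, disjoint
    across attributes) from the upper triangle; all remaining structure is
    the background mask/weights described in the module docstring.
    """
    spec.validate()
    if len(cohort) != spec.n_subjects:
        raise SpecValidationError(
            f"cohort has {len(cohort)} rows, spec expects {spec.n_subjects}"
        )
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(1,))
    rng = np.random.default_rng(ss)
    n, m = spec.n_subjects, spec.n_edges
    roi_labels = tuple(f"ROI_{i:03d}" for i in range(spec.n_rois))
    edge_pairs = edge_index_for(roi_labels)

    # fixed random mask of present edges, shared across subjects
    mask = rng.random(m) < spec.edge_density
    values = np.zeros((n, m))
    n_masked = int(mask.sum())
    values[:, mask] = rng.lognormal(
        mean=np.log(spec.base_weight_scale), sigma=LOGNORMAL_SIGMA, size=(n, n_masked)
    )

    # disjoint signal edges across attributes, uniform over the upper triangle
    total_signal = sum(spec.signal_edges_for(a) for a in spec.attribute_names)
    pool = rng.choice(m, size=total_signal, replace=False) if total_signal else np.array([], int)
    cursor = 0
    gt_rows = []
    for a in spec.attribute_specs:
        k = spec.signal_edges_for(a.name)
        rho = spec.rho_for(a.name)
        edges = pool[cursor : cursor + k]
        cursor += k
        b = cohort[a.name].to_numpy(dtype=float)
        sigma_b = b.std()
        for e in edges:
            eps = rng.normal(0.0, spec.noise_sd, size=n)
            if rho != 0.0 and sigma_b > 0:
                beta = rho * spec.noise_sd / (sigma_b * np.sqrt(1.0 - rho**2))
            else:
                beta = 0.0
            # offset pushes the negative tail ~4 sd below zero so clipping is
            # a <5e-5 event and the planted correlation survives undistorted
            total_sd = np.sqrt((beta * sigma_b) ** 2 + spec.noise_sd**2)
            raw = spec.base_weight_scale + 4.0 * total_sd + beta * (b - b.mean()) + eps
            clipped = np.clip(raw, 0.0, None)
            realized = _sample_r(clipped, b)
            # flag clipping that moved the correlation >10% off its analytic value
            warn = bool(
                np.any(raw < 0)
                and abs(realized - rho) > CLIP_WARNING_FRACTION * max(abs(rho), 1e-12)
            )
            values[:, e] = clipped
            i, j = edge_pairs[e]
            gt_rows.append(
                {
                    "attribute": a.name,
                    "edge_index": int(e),
                    "roi_a": i,
                    "roi_b": j,
                    "planted_rho": rho,
                    "realized_r": realized,
                    "clip_warning": warn,
                }
            )

    ground_truth = pd.DataFrame(
        gt_rows,
        columns=[
            "attribute", "edge_index", "roi_a", "roi_b",
            "planted_rho", "realized_r", "clip_warning",
        ],
    )
    iu, ju = np.triu_indices(spec.n_rois, k=1)
    matrices = []
    for row, sid in zip(values, cohort["subject_id"]):
        w = np.zeros((spec.n_rois, spec.n_rois))
        w[iu, ju] = row
        w[ju, iu] = row
        matrices.append(
            ConnectivityMatrix(subject_id=str(sid), weights=w, roi_labels=roi_labels)
        )
    return SyntheticCohort(
        spec=spec,
        matrices=matrices,
        cohort_table=cohort,
        ground_truth=ground_truth,
        seed_used=spec.seed,
        roi_labels=roi_labels,
        _edge_values=values,
    )


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Convenience: attributes then connectomes from one spec."""
    return generate_connectomes(spec, generate_attributes(spec))


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Persist a cohort in the formats the loaders read.

    Writes ``cohort.csv`` (metadata), ``ground_truth.csv`` (manifest) and
    one ``matrices/<subject_id>.csv`` square-matrix file per subject.
    """
    outdir = Path(outdir)
    (outdir / "matrices").mkdir(parents=True, exist_ok=True)
    cohort.cohort_table.to_csv(outdir / "cohort.csv", index=False)
    cohort.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
    for mat in cohort.matrices:
        write_matrix(mat, outdir / "matrices" / f"{mat.subject_id}.csv", "square_csv")
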