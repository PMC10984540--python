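"""End-to-end orchestration: simulate/load -> cross-validate -> compare.

A run is described by a :class:`RunConfig` (single YAML/JSON file) and is a
deterministic function of its global seed.  The seed fans out through
``numpy.random.SeedSequence`` spawn keys — cohort attributes use
``(0,)``, condition c's connectomes ``(1, c)``, and each cross-validation
derives its fold seed from ``(2, condition, attribute, subgroup)`` — so
every stage is individually reproducible.  All randomness flows through
explicitly passed generators/seeds; no global state is touched.

Outputs (all CSV + a JSON manifest) mirror the presentation of a
connectome prediction study: per-attribute metric tables with total /
male / female rows per dataset, per-dataset extreme edge-attribute
correlations, one BH-corrected comparison family per (attribute,
subgroup), and per-dataset attribute-pair comparisons.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cbr import edge_attribute_correlations, extreme_correlations
from .evaluation import CvResult, compute_metrics, kfold_split, cross_validate, subgroup_metrics
from .io import (
    DesignMatrix,
    assemble_design_matrix,
    read_cohort_table,
    read_matrix,
)
from .synthetic import (
    ADNI_ATTRIBUTES,
    HCP_ATTRIBUTES,
    AttributeSpec,
    CohortSpec,
    generate_attributes,
    generate_connectomes,
    write_cohort,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class RunConfig:
    """Validated configuration for a full analysis run.

    Synthetic mode generates ``n_conditions`` connectome datasets over one
    shared cohort (paired design, as when the same subjects are processed
    by several pipelines/parcellations); files mode reads matrices and
    cohort metadata from disk.
    """

    mode: str = "synthetic"  # "synthetic" | "files"
    out: str = "results/run"
    seed: int = 0
    attributes: tuple[str, ...] = ("age",)
    k: int = 10
    subgroups: str = "all"  # "all" | "by_sex"
    fdr_q: float = 0.05
    feature_pairs: tuple[tuple[str, str], ...] = ()
    # synthetic mode
    cohort_preset: str = "hcp"  # "hcp" | "adni"
    n_subjects: int = 300
    n_rois: int = 30
    n_conditions: int = 2
    n_signal_edges: Any = 5
    planted_rho: Any = 0.3
    noise_sd: float = 100.0
    edge_density: float = 0.3
    base_weight_scale: float = 100.0
    write_matrices: bool = False
    # files mode: [{"label": ..., "matrices_dir": ..., "dialect": ...}]
    conditions: tuple[dict, ...] = ()
    cohort_csv: str = ""

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in raw.items()})
        cfg.attributes = tuple(cfg.attributes)
        cfg.feature_pairs = tuple(tuple(p) for p in cfg.feature_pairs)
        cfg.conditions = tuple(dict(c) for c in cfg.conditions)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw or {})

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise PipelineError(f"config: mode must be synthetic|files, got {self.mode!r}")
        if self.subgroups not in ("all", "by_sex"):
            raise PipelineError("config: subgroups must be 'all' or 'by_sex'")
        if self.k < 2:
            raise PipelineError("config: k must be >= 2")
        if not self.attributes:
            raise PipelineError("config: attributes must be non-empty")
        if self.mode == "synthetic":
            preset = {"hcp": HCP_ATTRIBUTES, "adni": ADNI_ATTRIBUTES}.get(self.cohort_preset)
            if preset is None:
                raise PipelineError(f"config: unknown cohort_preset {self.cohort_preset!r}")
            names = {a.name for a in preset}
            for attr in self.attributes:
                if attr not in names:
                    raise PipelineError(
                        f"config: attribute {attr!r} not in cohort preset "
                        f"{self.cohort_preset!r} (has {sorted(names)})"
                    )
            if self.n_conditions < 1:
                raise PipelineError("config: n_conditions must be >= 1")
        else:
            if not self.conditions or not self.cohort_csv:
                raise PipelineError("config: files mode needs conditions and cohort_csv")
        for pair in self.feature_pairs:
            for attr in pair:
                if attr not in self.attributes:
                    raise PipelineError(
                        f"config: feature_pairs attribute {attr!r} not among attributes"
                    )

    def attribute_specs(self) -> tuple[AttributeSpec, ...]:
        return HCP_ATTRIBUTES if self.cohort_preset == "hcp" else ADNI_ATTRIBUTES


def _derived_seed(base: int, *key: int) -> int:
    """Deterministic 31-bit stage seed from the global seed and a spawn key."""
    state = np.random.SeedSequence(entropy=base, spawn_key=key).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


def _load_conditions(
    config: RunConfig, outdir: Path
) -> tuple[pd.DataFrame, dict[str, DesignMatrix]]:
    """Stage 1: produce the cohort table and one design matrix per condition."""
    if config.mode == "files":
        cohort = read_cohort_table(config.cohort_csv, required=config.attributes)
        designs: dict[str, DesignMatrix] = {}
        for cond in config.conditions:
            label = cond["label"]
            dialect = cond.get("dialect", "square_csv")
            mdir = Path(cond["matrices_dir"])
            mats = [
                read_matrix(p, dialect=dialect)
                for p in sorted(mdir.glob("*.csv")) + sorted(mdir.glob("*.txt"))
            ]
            if not mats:
                raise PipelineError(f"stage load: no matrix files under {mdir}")
            designs[label] = assemble_design_matrix(mats, cohort)
        return cohort, designs

    sex_frac = 564 / 1048 if config.cohort_preset == "hcp" else 54 / 94
    base_spec = CohortSpec(
        n_subjects=config.n_subjects,
        n_rois=config.n_rois,
        attribute_specs=config.attribute_specs(),
        sex_fraction_female=sex_frac,
        n_signal_edges=config.n_signal_edges,
        planted_rho=config.planted_rho,
        noise_sd=config.noise_sd,
        edge_density=config.edge_density,
        base_weight_scale=config.base_weight_scale,
        seed=_derived_seed(config.seed, 0),
    )
    cohort = generate_attributes(base_spec)
    designs = {}
    from dataclasses import replace

    for c in range(config.n_conditions):
        cond_spec = replace(base_spec, seed=_derived_seed(config.seed, 1, c))
        # the shared cohort table keeps the design paired across conditions
        syn = generate_connectomes(cond_spec, cohort)
        label = f"condition_{c}"
        designs[label] = syn.design_matrix()
        if config.write_matrices:
            write_cohort(syn, outdir / "cohorts" / label)
        syn.ground_truth.to_csv(outdir / f"ground_truth_{label}.csv", index=False)
    cohort.to_csv(outdir / "cohort.csv", index=False)
    return cohort, designs


def run_full_analysis(config: RunConfig) -> dict:
    """Execute all stages and write tables + manifest under ``config.out``.

    Returns the manifest dict.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    config.validate()
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    logger.info("stage simulate/load: preparing conditions")
    try:
        cohort, designs = _load_conditions(config, outdir)
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive wrapper
        raise PipelineError(f"stage simulate/load failed: {exc}") from exc

    subgroups = ["all"] if config.subgroups == "all" else ["all", "male", "female"]
    sub_index = {"all": 0, "male": 1, "female": 2}

    # stage 2: cross-validated metrics per condition x attribute x subgroup
    logger.info("stage evaluate: cross-validation over %d conditions", len(designs))
    cv_store: dict[tuple[str, str, str], CvResult] = {}
    metric_rows = []
    extreme_rows = []
    for ci, (label, A) in enumerate(designs.items()):
        for ai, attr in enumerate(config.attributes):
            if attr not in cohort.columns:
                raise PipelineError(f"stage evaluate: attribute {attr!r} missing from cohort")
            R_full = edge_attribute_correlations(A, cohort[attr].to_numpy(float), attr)
            lo, hi = extreme_correlations(R_full)
            extreme_rows.append(
                {"dataset": label, "attribute": attr, "min_r": lo, "max_r": hi}
            )
            for sub in subgroups:
                seed = _derived_seed(config.seed, 2, ci, ai, sub_index[sub])
                try:
                    cv, report = subgroup_metrics(
                        A, cohort, attr, sex=sub, k=config.k,
                        seed=seed, dataset_label=label,
                    )
                except ValueError as exc:
                    raise PipelineError(f"stage evaluate ({label}/{attr}/{sub}): {exc}")
                cv_store[(label, attr, sub)] = cv
                cv.records.assign(dataset=label, attribute=attr, subgroup=sub).to_csv(
                    outdir / f"cv_{label}_{attr}_{sub}.csv", index=False
                )
                metric_rows.append(
                    {
                        "dataset": label, "attribute": attr, "subgroup": sub,
                        "n": report.n, "r": report.pearson_r, "p": report.pearson_p,
                        "mae": report.mae, "mae_sd": report.mae_sd,
                        "nmae": report.nmae, "range_used": report.range_used,
                    }
                )
    metrics = pd.DataFrame(metric_rows)
    metrics.to_csv(outdir / "metrics.csv", index=False)
    pd.DataFrame(extreme_rows).to_csv(outdir / "extreme_correlations.csv", index=False)

    # stage 3: paired comparisons with BH correction
    logger.info("stage compare: paired signed-rank families")
    from .stats import compare_across_conditions, feature_pair_family

    family_files = []
    if len(designs) >= 2:
        for attr in config.attributes:
            for sub in subgroups:
                results = [cv_store[(label, attr, sub)] for label in designs]
                fam = compare_across_conditions(
                    results, family_label=f"{attr}_{sub}", q=config.fdr_q
                )
                fname = f"comparisons_{attr}_{sub}.csv"
                fam.to_frame().to_csv(outdir / fname, index=False)
                family_files.append(fname)
    for attr_a, attr_b in config.feature_pairs:
        for sub in subgroups:
            pairs = [
                (cv_store[(label, attr_a, sub)], cv_store[(label, attr_b, sub)])
                for label in designs
            ]
            fam = feature_pair_family(
                pairs, q=config.fdr_q, label=f"{attr_a}_vs_{attr_b}_{sub}"
            )
            fname = f"feature_pair_{attr_a}_vs_{attr_b}_{sub}.csv"
            fam.to_frame().to_csv(outdir / fname, index=False)
            family_files.append(fname)

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": _config_as_dict(config),
        "n_subjects": int(len(cohort)),
        "conditions": list(designs),
        "elapsed_seconds": round(time.time() - t0, 3),
        "outputs": {},
    }
    for path in sorted(outdir.glob("*.csv")):
        manifest["outputs"][path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("run complete in %.1fs -> %s", time.time() - t0, outdir)
    return manifest


def _config_as_dict(config: RunConfig) -> dict:
    out = {}
    for name in config.__dataclass_fields__:
        value = getattr(config, name)
        if isinstance(value, tuple):
            value = [list(v) if isinstance(v, tuple) else v for v in value]
        out[name] = value
    return out
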