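"""End-to-end pipeline driver with a machine-readable run report.

Wraps :class:`~protsig.model.SubtypeSignatureModel` with file I/O: read or
simulate the inputs, preprocess, fit, validate against the clinical table,
and persist every stage's outputs plus a JSON report.  A single global
seed fans out to per-stage sub-seeds (stable hash of seed + stage name),
so any stage can be reproduced in isolation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import bpso_select, synthetic_data
from .io_preprocess import (
    ClinicalTable,
    InputError,
    ProteinMatrix,
    filter_missing_proteins,
    impute_missing_mean,
    load_clinical_table,
    load_protein_matrix,
    merge_clinical,
    subset_by_classes,
)
from .model import SubtypeSignatureModel, derive_seed

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serializable to/from JSON."""

    expression_path: str | None = None
    clinical_path: str | None = None
    synthetic: dict | None = None        # SyntheticConfig fields
    classes: tuple[str, str] | None = None
    id_column: str = "Sample_ID"
    type_column: str = "Cancer_Type"
    clinical_id_column: str = "sample"
    id_match_len: int = 15
    max_missing_frac: float = 0.5
    snr_threshold: float = 0.4
    n_particles: int = 500
    n_iterations: int = 50
    w: float = 0.5
    c1: float = 1.0
    c2: float = 2.0
    base_learner: str = "knn"
    cv_folds: int = 5
    size_penalty: float = 0.01
    alpha: float = 0.05
    ci_method: str = "fisher_z"
    validation_tests: list[str] = field(
        default_factory=lambda: ["wilcoxon", "spearman", "cox"]
    )
    out_dir: str = "protsig_out"
    seed: int | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if "classes" in raw and raw["classes"] is not None:
            raw["classes"] = tuple(raw["classes"])
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _load_inputs(cfg: RunConfig) -> tuple[ProteinMatrix, ClinicalTable | None]:
    if cfg.synthetic is not None:
        syn = dict(cfg.synthetic)
        if "informative" in syn:
            syn["informative"] = [tuple(t) for t in syn["informative"]]
        if "dag_spec" in syn and syn["dag_spec"] is not None:
            syn["dag_spec"] = [tuple(t) for t in syn["dag_spec"]]
        if "survival" in syn and isinstance(syn["survival"], dict):
            syn["survival"] = synthetic_data.SurvivalSpec(**syn["survival"])
        syn.setdefault("seed", derive_seed(cfg.seed, "simulate"))
        scfg = synthetic_data.SyntheticConfig(**syn)
        pm, _ = synthetic_data.generate_expression(scfg)
        clinical = synthetic_data.generate_clinical(scfg, pm)
        return pm, clinical
    if cfg.expression_path is None:
        raise InputError("config needs expression_path or synthetic")
    pm = load_protein_matrix(cfg.expression_path, cfg.id_column, cfg.type_column)
    clinical = (
        load_clinical_table(cfg.clinical_path, cfg.clinical_id_column)
        if cfg.clinical_path
        else None
    )
    return pm, clinical


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute preprocess -> SNR -> BPSO -> PC-stable -> validation.

    Writes per-stage artifacts under ``cfg.out_dir`` and returns the run
    report (also saved as ``report.json``).  A stage failure aborts with
    the stage name attached to the exception.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}}
    stage = "load"
    try:
        t0 = time.time()
        pm, clinical = _load_inputs(cfg)
        report["stages"]["load"] = {
            "n_samples": pm.n_samples,
            "n_proteins": pm.n_proteins,
            "wall_time_s": round(time.time() - t0, 3),
        }

        stage = "preprocess"
        t0 = time.time()
        if cfg.classes is not None:
            pm = subset_by_classes(pm, list(cfg.classes))
        pm, dropped = filter_missing_proteins(pm, cfg.max_missing_frac)
        pm, imputed = impute_missing_mean(pm)
        if clinical is not None:
            merged = merge_clinical(pm, clinical, cfg.id_match_len)
            if merged.n_samples == 0 and cfg.id_match_len != 12:
                logger.warning("no ID matches at prefix %d; retrying with 12",
                               cfg.id_match_len)
                merged = merge_clinical(pm, clinical, 12)
            pm, clinical = merged.expression, merged.clinical
        pm.to_tsv(out / "preprocessed.tsv")
        report["stages"]["preprocess"] = {
            "n_samples": pm.n_samples,
            "n_proteins": pm.n_proteins,
            "dropped_proteins": dropped,
            "imputed_proteins": imputed,
            "wall_time_s": round(time.time() - t0, 3),
        }

        stage = "fit"
        t0 = time.time()
        model = SubtypeSignatureModel(
            pm,
            snr_threshold=cfg.snr_threshold,
            bpso_params=bpso_select.BPSOParams(
                n_particles=cfg.n_particles,
                n_iterations=cfg.n_iterations,
                w=cfg.w,
                c1=cfg.c1,
                c2=cfg.c2,
            ),
            fitness_spec=bpso_select.FitnessSpec(
                base_learner=cfg.base_learner,
                cv_folds=cfg.cv_folds,
                size_penalty=cfg.size_penalty,
            ),
            alpha=cfg.alpha,
            ci_method=cfg.ci_method,
        )
        results = model.fit(seed=cfg.seed)
        results.snr_scores.to_csv(out / "snr_scores.tsv", sep="\t")
        results.cpdag.edge_table().to_csv(out / "network_edges.tsv", sep="\t",
                                          index=False)
        results.save_report(out / "signature.json")
        report["stages"]["fit"] = {
            **{k: len(v) for k, v in results.marker_sets().items()},
            "bpso_fitness": results.selection.fitness,
            "wall_time_s": round(time.time() - t0, 3),
        }
        report["marker_sets"] = results.marker_sets()

        stage = "validate"
        t0 = time.time()
        validation: dict = {}
        if "wilcoxon" in cfg.validation_tests:
            tab = results.group_tests()
            tab.to_csv(out / "wilcoxon.tsv", sep="\t")
            validation["wilcoxon"] = tab.reset_index().to_dict(orient="records")
        if clinical is not None and "spearman" in cfg.validation_tests:
            tab = results.stage_correlations(clinical)
            tab.to_csv(out / "spearman_stage.tsv", sep="\t")
            validation["spearman"] = tab.reset_index().to_dict(orient="records")
        if clinical is not None and "cox" in cfg.validation_tests:
            tab = results.cox_table(clinical)
            tab.to_csv(out / "cox_univariate.tsv", sep="\t")
            validation["cox"] = tab.reset_index().to_dict(orient="records")
        if len(results.bpso_selected) >= 2:
            pca = results.pca_report(results.bpso_selected)
            validation["pca_variance_pct"] = [float(v) for v in pca.variance_pct[:2]]
        report["stages"]["validate"] = {"wall_time_s": round(time.time() - t0, 3)}
        report["validation"] = validation
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
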