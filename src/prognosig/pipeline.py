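"""End-to-end orchestration: simulate/load → normalize → DE → cluster →
rank → forward-select → calibrate → classify validation cohort → evaluate.

Every run writes its artifacts plus a machine-readable ``manifest.json``
recording the full configuration (every threshold actually applied, the
seed) and per-stage summaries; re-running with an identical configuration
reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import cut_two, hierarchical_cluster, svm_loocv
from .de import de_summary, select_de_genes, write_de_table
from .errors import ConfigurationError, DataError, PipelineStageError
from .evaluate import (
    EvaluationReport,
    auc_ci,
    fisher_exact,
    km_logrank,
    roc_auc,
    sens_spec,
)
from .io import (
    LESION_MALIGNANT,
    SCALE_RAW,
    normalize,
    read_expression,
    read_sample_annotation,
    write_expression,
    write_probe_annotation,
    write_sample_annotation,
)
from .signature import (
    classify,
    derive_outcome_labels,
    forward_select,
    outcome_correlations,
)
from .simulate import (
    GOOD,
    POOR,
    SimulationConfig,
    generate_dataset,
    generate_validation_cohort,
)

logger = logging.getLogger(__name__)

_LOG_FORMAT = "%(levelname)s %(name)s: %(message)s"  # no timestamps: outputs stay reproducible


def setup_logging(level: str = "INFO", log_path=None) -> None:
    handlers = [logging.StreamHandler()]
    if log_path is not None:
        handlers.append(logging.FileHandler(log_path, mode="w"))
    logging.basicConfig(level=getattr(logging, level.upper()), format=_LOG_FORMAT,
                        handlers=handlers, force=True)


@dataclass
class PipelineConfig:
    """A single configuration for the whole study-design pipeline."""

    # exactly one data source: a simulation block, or input paths
    simulate: SimulationConfig | None = None
    expression_path: str | None = None
    probe_annotation_path: str | None = None
    sample_annotation_path: str | None = None
    validation_expression_path: str | None = None
    validation_sample_annotation_path: str | None = None
    expression_scale: str = "log2"

    fc_min: float = 2.0
    p_max: float = 0.05
    r_min: float = 0.3
    batch: int = 5
    target_fnr: float = 0.13
    paired: bool = True
    outcome_coding: str = "cluster"  # cluster | metastasis
    svm_check: bool = True
    eval_cohort: str = "validation"  # validation | training
    n_boot: int = 2000

    out_dir: str = "prognosig_run"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        simulated = self.simulate is not None
        from_files = self.expression_path is not None
        if simulated == from_files:
            raise ConfigurationError(
                "exactly one of a simulate block or an expression_path must be given"
            )
        if simulated:
            self.simulate.validate()
        elif self.sample_annotation_path is None:
            raise ConfigurationError("sample_annotation_path is required with expression_path")
        if self.fc_min < 1:
            raise ConfigurationError(f"fc_min must be >= 1 (got {self.fc_min})")
        if not 0 < self.p_max <= 1:
            raise ConfigurationError(f"p_max must be in (0, 1] (got {self.p_max})")
        if not 0 <= self.r_min < 1:
            raise ConfigurationError(f"r_min must be in [0, 1) (got {self.r_min})")
        if self.batch < 1:
            raise ConfigurationError(f"batch must be >= 1 (got {self.batch})")
        if not 0 <= self.target_fnr < 1:
            raise ConfigurationError(f"target_fnr must be in [0, 1) (got {self.target_fnr})")
        if self.outcome_coding not in ("cluster", "metastasis"):
            raise ConfigurationError(f"unknown outcome_coding {self.outcome_coding!r}")
        if self.eval_cohort not in ("validation", "training"):
            raise ConfigurationError(f"unknown eval_cohort {self.eval_cohort!r}")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        sim = payload.get("simulate")
        if sim is not None and not isinstance(sim, SimulationConfig):
            payload["simulate"] = SimulationConfig(**sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**payload)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if not isinstance(payload, dict):
            raise ConfigurationError(f"{path}: expected a mapping at top level")
        return cls.from_dict(payload)


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    config: PipelineConfig
    out_dir: Path
    manifest: dict
    de_result: object = None
    sample_dendrogram: object = None
    gene_dendrogram: object = None
    clusters: object = None
    outcome_labels: pd.Series | None = None
    correlations: object = None
    signature: object = None
    report: EvaluationReport | None = None
    truth: object = None


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __init__(self, out_dir):
            self.out_dir = out_dir

        def __enter__(self):
            logger.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(
                    name, f"{exc} (partial results, if any, are under {self.out_dir})"
                ) from exc
            return False

    return _Ctx


def _derived_seed(seed: int, stream: int) -> int:
    """A per-stage integer seed derived deterministically from the run seed."""
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline; returns results and writes all artifacts."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config_record = config.to_dict()
    config_record.pop("out_dir")  # the output location is not provenance;
    # omitting it keeps manifests byte-identical across run directories
    manifest: dict = {
        "tool": {"name": "prognosig", "version": __version__},
        "config": config_record,
        "stages": {},
        "artifacts": [],
    }
    result = PipelineResult(config=config, out_dir=out_dir, manifest=manifest)

    def save(name, writer):
        path = out_dir / name
        writer(path)
        manifest["artifacts"].append(name)
        return path

    # ---- data -------------------------------------------------------------
    with _stage("data")(out_dir):
        if config.simulate is not None:
            matrix, annotation, truth = generate_dataset(config.simulate)
            val_matrix, val_annotation = generate_validation_cohort(config.simulate, truth)
            result.truth = truth
        else:
            matrix = read_expression(
                config.expression_path,
                config.probe_annotation_path,
                scale_tag=config.expression_scale,
            )
            annotation = read_sample_annotation(config.sample_annotation_path)
            if config.validation_expression_path is not None:
                val_matrix = read_expression(
                    config.validation_expression_path,
                    config.probe_annotation_path,
                    scale_tag=config.expression_scale,
                )
                val_annotation = read_sample_annotation(
                    config.validation_sample_annotation_path
                )
            else:
                val_matrix, val_annotation = None, None
        manifest["stages"]["data"] = {
            "n_probes": matrix.n_probes,
            "n_training_samples": matrix.n_samples,
            "n_validation_samples": 0 if val_matrix is None else val_matrix.n_samples,
            "source": "simulate" if config.simulate is not None else "files",
        }
        save("training_expression.tsv", lambda p: write_expression(matrix, p))
        save("probe_annotation.tsv", lambda p: write_probe_annotation(matrix, p))
        save("training_samples.tsv", lambda p: write_sample_annotation(annotation, p))
        if val_matrix is not None:
            save("validation_expression.tsv", lambda p: write_expression(val_matrix, p))
            save("validation_samples.tsv", lambda p: write_sample_annotation(val_annotation, p))

    # ---- normalize --------------------------------------------------------
    with _stage("normalize")(out_dir):
        if matrix.scale_tag == SCALE_RAW:
            matrix = normalize(matrix)
            if val_matrix is not None:
                val_matrix = normalize(val_matrix)
            manifest["stages"]["normalize"] = {"applied": True, "method": "log2 + median-centering"}
        else:
            manifest["stages"]["normalize"] = {"applied": False, "scale": matrix.scale_tag}

    # ---- differential expression -----------------------------------------
    with _stage("differential_expression")(out_dir):
        de_result = select_de_genes(
            matrix, annotation, fc_min=config.fc_min, p_max=config.p_max, paired=config.paired
        )
        result.de_result = de_result
        counts = de_summary(de_result)
        manifest["stages"]["differential_expression"] = {
            "fc_min": config.fc_min,
            "p_max": config.p_max,
            "paired": config.paired,
            "n_selected": counts.n_selected,
            "n_up": counts.n_up,
            "n_down": counts.n_down,
        }
        if counts.n_selected < 2:
            raise DataError("fewer than 2 differential probes selected; cannot continue")
        save("de_results.tsv", lambda p: write_de_table(de_result, p))

    # ---- prognostic clustering (+ SVM confirmation) ----------------------
    with _stage("clustering")(out_dir):
        tumors = annotation.loc[
            annotation["lesion"] == LESION_MALIGNANT, "sample_id"
        ].tolist()
        tumor_matrix = matrix.restrict(probes=de_result.selected_probes, samples=tumors)
        dend = hierarchical_cluster(tumor_matrix, axis="samples")
        gene_dend = hierarchical_cluster(tumor_matrix, axis="genes")
        clusters = cut_two(dend)
        result.sample_dendrogram, result.gene_dendrogram, result.clusters = dend, gene_dend, clusters
        stage_info = {
            "n_tumors": len(tumors),
            "n_probes": int(len(de_result.selected_probes)),
            "cluster_sizes": clusters.labels.value_counts().sort_index().tolist(),
        }
        if config.svm_check:
            lesion_labels = annotation.set_index("sample_id")["lesion"].reindex(
                matrix.sample_ids
            )
            svm = svm_loocv(matrix, lesion_labels, probe_ids=de_result.selected_probes)
            stage_info["svm_loocv_accuracy"] = svm.accuracy
            stage_info["svm_misclassified"] = svm.misclassified
        manifest["stages"]["clustering"] = stage_info
        save("tumor_dendrogram.nwk", lambda p: p.write_text(dend.to_newick() + "\n"))
        save("gene_dendrogram.nwk", lambda p: p.write_text(gene_dend.to_newick() + "\n"))
        save(
            "clusters.tsv",
            lambda p: clusters.labels.rename("cluster")
            .rename_axis("sample_id")
            .to_csv(p, sep="\t"),
        )

    # ---- outcome labels + correlation ranking ----------------------------
    with _stage("outcome_correlation")(out_dir):
        outcome = derive_outcome_labels(clusters, annotation, coding=config.outcome_coding)
        result.outcome_labels = outcome
        tumor_expr = tumor_matrix.values
        correlations = outcome_correlations(tumor_expr, outcome, r_min=config.r_min)
        result.correlations = correlations
        manifest["stages"]["outcome_correlation"] = {
            "coding": config.outcome_coding,
            "r_min": config.r_min,
            "n_good": int((outcome == GOOD).sum()),
            "n_poor": int((outcome == POOR).sum()),
            "n_pool": int(len(correlations.ranked)),
        }
        save(
            "outcome_correlations.tsv",
            lambda p: correlations.ranked.rename_axis("probe_id").to_csv(
                p, sep="\t", float_format="%.6g"
            ),
        )

    # ---- forward selection + threshold calibration -----------------------
    with _stage("signature_selection")(out_dir):
        signature = forward_select(
            tumor_expr,
            outcome,
            correlations,
            batch=config.batch,
            target_fnr=config.target_fnr,
        )
        result.signature = signature
        manifest["stages"]["signature_selection"] = {
            "batch": config.batch,
            "target_fnr": config.target_fnr,
            "size": signature.size,
            "loocv_accuracy": signature.loocv_accuracy,
            "threshold": signature.threshold,
            "achieved_fnr": signature.achieved_fnr,
            "accuracy_curve": [[int(s), float(a)] for s, a in signature.accuracy_curve],
        }
        save("signature.tsv", lambda p: signature.to_table().to_csv(p, sep="\t", float_format="%.6g"))
        save("signature.json", lambda p: p.write_text(signature.to_json() + "\n"))

    # ---- validation-cohort classification + evaluation -------------------
    with _stage("evaluation")(out_dir):
        report = EvaluationReport(threshold=signature.threshold)
        if config.eval_cohort == "validation" and (
            val_matrix is None or val_matrix.n_samples == 0
        ):
            report.flags.append("no validation cohort; evaluation skipped")
        else:
            if config.eval_cohort == "validation":
                eval_expr = val_matrix.values
                eval_annotation = val_annotation
            else:
                eval_expr = tumor_expr
                eval_annotation = annotation[annotation["lesion"] == LESION_MALIGNANT]
            scores, calls = classify(eval_expr, signature)
            ann = eval_annotation.set_index("sample_id").loc[scores.index]
            # observable outcome labels: no 5-year metastasis = good prognosis
            observed = pd.Series(
                np.where(ann["metastasis_5yr"] == "no", GOOD, POOR), index=scores.index
            )
            report.extras["ci_scores"] = {k: float(v) for k, v in scores.items()}
            report.extras["calls"] = {k: str(v) for k, v in calls.items()}
            try:
                points, auc = roc_auc(scores.values, observed.values)
                report.roc_points = points.tolist()
                report.auc = auc
                report.auc_ci = auc_ci(
                    scores.values,
                    observed.values,
                    n_boot=config.n_boot,
                    seed=_derived_seed(config.seed, 1),
                )
                report.sensitivity, report.specificity = sens_spec(
                    scores.values, observed.values, signature.threshold
                )
            except DataError as exc:
                report.flags.append(f"ROC skipped: {exc}")
            per_patient = ann.reset_index().set_index("patient_id")
            call_by_patient = pd.Series(calls.values, index=per_patient.index)
            try:
                curves, stat, p = km_logrank(per_patient, call_by_patient)
                report.km_curves = curves
                report.logrank_stat, report.logrank_p = stat, p
                report.logrank_defined = bool(np.isfinite(p))
                if not report.logrank_defined:
                    report.flags.append("log-rank undefined: no observed events")
            except DataError as exc:
                report.flags.append(f"log-rank skipped: {exc}")
            table = [
                [
                    int(((calls == GOOD) & (observed == GOOD)).sum()),
                    int(((calls == GOOD) & (observed == POOR)).sum()),
                ],
                [
                    int(((calls == POOR) & (observed == GOOD)).sum()),
                    int(((calls == POOR) & (observed == POOR)).sum()),
                ],
            ]
            odds, fisher_p = fisher_exact(np.array(table))
            report.fisher_tables.append(
                {"table": table, "odds_ratio": odds, "p": fisher_p,
                 "rows": "call good/poor", "cols": "observed good/poor"}
            )
            if result.truth is not None:
                truth_groups = result.truth.patient_groups.reindex(per_patient.index)
                accuracy = float((calls.values == truth_groups.values).mean())
                report.extras["accuracy_vs_planted_groups"] = accuracy
        result.report = report
        manifest["stages"]["evaluation"] = {
            "cohort": config.eval_cohort,
            "auc": report.auc,
            "auc_ci": list(report.auc_ci),
            "sensitivity": report.sensitivity,
            "specificity": report.specificity,
            "logrank_p": report.logrank_p,
            "flags": report.flags,
            **(
                {"accuracy_vs_planted_groups": report.extras["accuracy_vs_planted_groups"]}
                if "accuracy_vs_planted_groups" in report.extras
                else {}
            ),
        }
        save("evaluation.json", lambda p: p.write_text(report.to_json() + "\n"))

    # ---- manifest ---------------------------------------------------------
    manifest_json = json.dumps(manifest, indent=2, sort_keys=True, default=_json_default)
    (out_dir / "manifest.json").write_text(manifest_json + "\n")
    return result


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "setup_logging"]
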