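"""End-to-end orchestration of the five-stage workflow.

Stage order: parse -> assemble -> categorize/mask -> normalize -> filter ->
impute -> differential expression, producing exactly seven output files
(four TSV tables, three PNG figures) plus a run log and a JSON manifest.
A stage failure aborts with the stage name; outputs produced up to that
point are kept and listed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import categorize, diffexp, filter_impute, normalize, qc_report, qpcr_io

__all__ = ["PipelineConfig", "PipelineError", "StageError", "run_pipeline", "OUTPUT_NAMES"]

log = logging.getLogger(__name__)

OUTPUT_NAMES = {
    "raw_ct": "01_raw_ct.tsv",
    "boxplot_pre": "02_boxplot_pre_normalization.png",
    "normalized": "03_normalized_ct.tsv",
    "cv_ecdf": "04_cv_ecdf.png",
    "boxplot_post": "05_boxplot_post_normalization.png",
    "imputed": "06_imputed_ct.tsv",
    "diffexp": "07_differential_expression.tsv",
}


class PipelineError(RuntimeError):
    pass


class StageError(PipelineError):
    def __init__(self, stage: str, cause: Exception, partial: dict):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.partial_outputs = partial


@dataclass
class PipelineConfig:
    input_files: list
    treatment_path: str
    output_dir: str
    dialect: str = "Plain"
    category: categorize.CategorySettings = field(
        default_factory=categorize.CategorySettings)
    normalization: normalize.NormalizationSpec = field(
        default_factory=normalize.NormalizationSpec)
    filter: filter_impute.FilterSpec = field(default_factory=filter_impute.FilterSpec)
    imputation: filter_impute.ImputeSpec = field(default_factory=filter_impute.ImputeSpec)
    de: diffexp.DESpec = field(default_factory=diffexp.DESpec)
    filter_first: bool = False
    impute_before_normalize: bool = False
    seed: int | None = None

    def validate(self):
        for f in self.input_files:
            if not Path(f).is_file():
                raise PipelineError(f"input file not found: {f}")
        if not Path(self.treatment_path).is_file():
            raise PipelineError(f"treatment file not found: {self.treatment_path}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns a manifest of output paths and run facts."""
    cfg.validate()
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {k: out_dir / v for k, v in OUTPUT_NAMES.items()}
    log_path = out_dir / "run.log"

    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("ctpipe")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    outputs: dict[str, str] = {}
    manifest: dict = {"outputs": outputs, "log": str(log_path)}
    stage = "parse"
    try:
        log.info("config: dialect=%s category=%s normalization=%s filter=%s "
                 "imputation=%s de=%s seed=%s", cfg.dialect, cfg.category,
                 cfg.normalization, cfg.filter, cfg.imputation, cfg.de, cfg.seed)
        treatment = qpcr_io.parse_treatment_file(cfg.treatment_path)
        records = {}
        by_name = {Path(f).name: f for f in cfg.input_files}
        for sample in treatment.sample_names:
            if sample not in by_name:
                raise qpcr_io.AssemblyError(
                    f"treatment file sample {sample!r} has no matching input file")
            records[sample] = qpcr_io.parse_ct_file(by_name[sample], cfg.dialect)
        log.info("parsed %d samples (calibrator group %s, target group %s)",
                 len(records), treatment.calibrator_group, treatment.target_group)

        stage = "assemble"
        ds = qpcr_io.assemble_dataset(records, treatment)

        stage = "categorize"
        ds = categorize.assign_categories(ds, cfg.category)
        masked = categorize.mask_unreliable(ds)
        qpcr_io.write_ct_table(ds, paths["raw_ct"])
        outputs["raw_ct"] = str(paths["raw_ct"])
        qc_report.render_boxplots(masked, paths["boxplot_pre"],
                                  title="Ct distribution after categorization")
        outputs["boxplot_pre"] = str(paths["boxplot_pre"])

        working = masked
        removed: list[str] = []
        if cfg.filter_first:
            stage = "filter"
            working, removed = filter_impute.filter_features(working, cfg.filter)
        if cfg.impute_before_normalize:
            stage = "impute"
            working = filter_impute.apply_imputation(working, cfg.imputation)

        stage = "normalize"
        normalized, stability = normalize.apply_normalization(
            working, cfg.normalization, treatment)
        if stability is not None:
            log.info("selected housekeepers (%s): %s", stability.method,
                     stability.selected)
            manifest["housekeepers"] = list(stability.selected)
        qpcr_io.write_ct_table(normalized, paths["normalized"])
        outputs["normalized"] = str(paths["normalized"])

        stage = "qc"
        report = qc_report.build_qc_report(masked, normalized)
        log.info("KS D=%.4f p=%.4g", report.ks_D, report.ks_p)
        manifest["ks_D"] = report.ks_D
        manifest["ks_p"] = report.ks_p
        qc_report.render_ecdf(report, paths["cv_ecdf"])
        outputs["cv_ecdf"] = str(paths["cv_ecdf"])
        qc_report.render_boxplots(normalized, paths["boxplot_post"],
                                  title="Ct distribution after normalization")
        outputs["boxplot_post"] = str(paths["boxplot_post"])
        report.summaries_pre.to_csv(out_dir / "boxplot_pre_summary.tsv",
                                    sep="\t", index=False)
        report.summaries_post.to_csv(out_dir / "boxplot_post_summary.tsv",
                                     sep="\t", index=False)

        working = normalized
        if not cfg.filter_first:
            stage = "filter"
            working, removed = filter_impute.filter_features(working, cfg.filter)
        manifest["removed_features"] = removed
        log.info("%d features removed by filtering", len(removed))

        if not cfg.impute_before_normalize:
            stage = "impute"
            working = filter_impute.apply_imputation(working, cfg.imputation)
        qpcr_io.write_ct_table(working, paths["imputed"])
        outputs["imputed"] = str(paths["imputed"])

        stage = "diffexp"
        de_spec = cfg.de
        if de_spec.seed is None and cfg.seed is not None:
            de_spec = diffexp.DESpec(**{**de_spec.__dict__, "seed": cfg.seed})
        table = diffexp.run_diffexp(working, treatment, de_spec)
        if table is None:
            # method NONE: header-only table so all seven outputs exist
            stat = {"ttest": "t.test", "wilcoxon": "W", "rankprod": "RP"}.get(
                de_spec.method, "t.test")
            cols = [c.format(stat=stat) for c in diffexp.RESULT_COLUMNS]
            with open(paths["diffexp"], "w", encoding="utf-8") as fh:
                fh.write("\t".join(cols) + "\n")
            manifest["de_method"] = "none"
            log.info("differential expression skipped (method NONE)")
        else:
            table.to_csv(paths["diffexp"], sep="\t", index=False, na_rep="NA")
            manifest["de_method"] = de_spec.method
        outputs["diffexp"] = str(paths["diffexp"])

        manifest["n_features"] = working.n_features
        manifest["n_samples"] = working.n_samples
        with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)
        return manifest
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        log.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc, dict(outputs)) from exc
    finally:
        root.removeHandler(handler)
        handler.close()
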