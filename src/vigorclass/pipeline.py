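"""One-command orchestration: QC -> impute -> GRM -> fit -> CV -> GWAS/LD.

Every stage writes its outputs under the run directory as plain TSV/JSON so
each reported number can be recomputed from persisted stage outputs. A
single global seed is expanded into per-stage seeds by hashing the stage
name (CRC-32) together with the global seed through a SeedSequence, so any
stage can be re-run in isolation with the same stream.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .association_ld import (
    effects_frame,
    large_effect_markers,
    ld_matrix,
    ld_summaries,
    single_snp_scan,
)
from .crossval import per_line_error_summary, run_repeated_cv
from .genotype_io import load_genotypes, phenotype_vector, qc_filter, write_panel
from .grm import compute_grm, grm_summary, write_grm
from .imputation import accuracy_experiment, impute_missing, interpolate_accuracy
from .threshold_model import classify, fit_threshold_model, likelihood_ratio_test


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclasses.dataclass
class RunConfig:
    genotypes: str
    marker_map: str | None = None
    samples: str | None = None
    format: str = "table"
    max_snp_missing: float = 0.15
    min_maf: float = 0.025
    cv_k: int = 5
    cv_repeats: int = 10
    fixed_h2_grid: list | None = None
    impute_fractions: list | None = None  # run the masking experiment if set
    impute_replicates: int = 5
    interpolate_at: float | None = None
    seed: int = 0
    outdir: str = "vigorclass_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis flow; returns the run-summary dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"vigorclass {__version__}", f"seed {config.seed}"]
    report: dict = {"seed": config.seed, "version": __version__}

    def log(msg):
        log_lines.append(msg)

    def persist():
        (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
        (out / "run_summary.json").write_text(json.dumps(report, indent=1, default=str))

    stage = "load"
    try:
        panel = load_genotypes(
            config.genotypes,
            format=config.format,
            marker_map=config.marker_map,
            samples=config.samples,
        )
        log(f"loaded {panel.n_samples} samples x {panel.n_markers} markers")

        stage = "qc"
        panel, qc_report = qc_filter(
            panel, max_snp_missing=config.max_snp_missing, min_maf=config.min_maf
        )
        (out / "qc_report.txt").write_text(qc_report.summary() + "\n")
        report["qc"] = {
            "n_samples": qc_report.n_samples_after,
            "n_markers": qc_report.n_markers_after,
            "n_missing": qc_report.n_missing_remaining,
            "n_cells": qc_report.n_cells_remaining,
            "missing_percent": qc_report.missing_percent,
        }
        log(qc_report.summary())

        stage = "impute"
        if not panel.is_complete:
            imp = impute_missing(panel)
            panel = imp.panel
            report["imputation"] = {
                "n_imputed": int(imp.imputed_mask.sum()),
                "n_fallback": imp.n_fallback,
            }
            log(f"imputed {int(imp.imputed_mask.sum())} cells "
                f"({imp.n_fallback} modal fallbacks)")
        write_panel(
            panel,
            out / "panel_genotypes.tsv",
            out / "panel_markers.tsv",
            out / "panel_samples.tsv",
        )

        stage = "grm"
        grm = compute_grm(panel)
        write_grm(grm, out / "grm.tsv", out / "grm_meta.json")
        summ = grm_summary(grm, panel.samples)
        report["grm"] = {
            "mean_offdiag": summ.mean_offdiag,
            "sd_offdiag": summ.sd_offdiag,
            "cv_offdiag_percent": summ.cv_offdiag,
            "mean_all": summ.mean_all,
            "mean_diag": summ.mean_diag,
            "closest_lines": summ.closest_pair,
            "farthest_lines": summ.farthest_pair,
        }
        summ.line_block_means.to_csv(out / "grm_line_blocks.tsv", sep="\t")
        log(str(summ))

        stage = "fit"
        y = phenotype_vector(panel)
        fit = fit_threshold_model(y, grm, mode="estimate", compute_se=True)
        lrt = likelihood_ratio_test(fit)
        report["fit"] = fit.summary()
        report["fit"]["lrt_statistic"] = lrt.statistic
        report["fit"]["lrt_p_value"] = lrt.p_value
        probs = classify(fit)
        with open(out / "fit_predictions.tsv", "w") as fh:
            fh.write("sample_id\tg\tp_high\tpredicted_class\n")
            for c, g in zip(probs, fit.g):
                fh.write(f"{c.sample_id}\t{g:.6g}\t{c.p_high:.6g}\t{c.predicted_class}\n")
        log(
            f"h2 = {fit.h2:.3f} (sigma_a2 = {fit.sigma_a2:.3f}); "
            f"LRT stat {lrt.statistic:.2f}, p = {lrt.p_value:.3g}; "
            f"converged = {fit.converged}"
        )

        stage = "cv"
        cv = run_repeated_cv(
            panel,
            grm,
            k=config.cv_k,
            repeats=config.cv_repeats,
            rng_seed=stage_seed(config.seed, "cv"),
        )
        report["cv"] = {
            "cv_error": cv.cv_error,
            "pooled_error": cv.pooled_error,
            "n_misclassified": cv.n_misclassified,
            "n_test_total": cv.n_test_total,
            "n_replicates": len(cv.replicate_errors),
            "n_skipped": cv.n_skipped,
        }
        np.savetxt(out / "cv_replicate_errors.tsv", cv.replicate_errors, fmt="%.6g")
        per_line_error_summary(cv).to_csv(out / "cv_per_line.tsv", sep="\t", index=False)
        log(f"CV error {cv.cv_error:.4g} ({cv.n_misclassified}/{cv.n_test_total} pooled)")

        if config.fixed_h2_grid:
            stage = "cv_fixed_h2"
            sweep = {}
            for h2 in config.fixed_h2_grid:
                cvh = run_repeated_cv(
                    panel,
                    grm,
                    k=config.cv_k,
                    repeats=config.cv_repeats,
                    mode="fixed_h2",
                    h2_fixed=float(h2),
                    rng_seed=stage_seed(config.seed, f"cv_h2_{h2}"),
                )
                sweep[str(h2)] = {
                    "cv_error": cvh.cv_error,
                    "median_error": float(np.median(cvh.replicate_errors)),
                }
                log(f"fixed h2={h2}: CV error {cvh.cv_error:.4g}")
            report["cv_fixed_h2"] = sweep

        stage = "gwas"
        effects = single_snp_scan(panel)
        effects_frame(effects).to_csv(out / "snp_effects.tsv", sep="\t", index=False)
        large = large_effect_markers(effects)

        stage = "ld"
        ld = ld_matrix(panel)
        lds = ld_summaries(ld, panel.markers, large_effect_ids=large)
        report["ld"] = dataclasses.asdict(lds)
        report["ld"]["n_large_effect_markers"] = len(large)
        log(
            f"LD r2: total {lds.mean_total:.3f}, within-scaffold "
            f"{lds.mean_within_scaffold}, large-effect {lds.mean_large_effect}"
        )

        if config.impute_fractions:
            stage = "impute_accuracy"
            exp = accuracy_experiment(
                panel,
                fractions=config.impute_fractions,
                replicates=config.impute_replicates,
                rng_seed=stage_seed(config.seed, "impute_accuracy"),
            )
            exp.per_replicate.to_csv(out / "imputation_accuracy.tsv", sep="\t", index=False)
            report["imputation_accuracy"] = dict(
                zip(map(str, exp.missing_fractions), exp.accuracies)
            )
            if config.interpolate_at is not None:
                report["imputation_accuracy_at"] = {
                    "fraction": config.interpolate_at,
                    "accuracy": interpolate_accuracy(exp, config.interpolate_at),
                }
    except Exception as e:  # persist whatever completed, then re-raise with stage
        log(f"FAILED at stage {stage}: {e}")
        persist()
        raise PipelineError(stage, e) from e

    persist()
    return report
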