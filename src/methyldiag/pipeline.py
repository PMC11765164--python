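"""End-to-end pipeline: simulate/load -> tissue screen -> disease ranking ->
summaries -> model training -> cross-validated evaluation.

One flat YAML config drives the run; every stage writes its table under the
output directory, a run log records seeds, parameters, timings and the
sample/site counts surviving each stage, and a manifest lists every artifact
so any single stage can be re-run from it.  Re-running the same config
reproduces identical tables.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import io as mio
from .evaluation import crossval_evaluate
from .model import DiagnosisModel, TrainConfig, compatible_heads, train_model
from .screening import (
    DEFAULT_N_BINS,
    DEFAULT_TAU_P,
    DEFAULT_TOP_K,
    rank_disease_sites,
    screen_tissue_specific,
    site_summary,
)
from .simulate import SyntheticCohortConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("methyldiag")


@dataclass
class PipelineConfig:
    """Flat configuration for :func:`run_pipeline`.

    Either ``synthetic`` (a SyntheticCohortConfig field mapping) or both
    ``betas_path`` and ``metadata_path`` must be given.  All screening /
    ranking / model constants surface here with their standard defaults
    (tau_p 0.01, 10 bins, top 400 sites, 5 folds).
    """

    output_dir: str = "methyldiag_run"
    seed: int = 0
    betas_path: str | None = None
    metadata_path: str | None = None
    synthetic: dict[str, Any] | None = None
    tissue_vocabulary: list[str] | None = None
    tau_p: float = DEFAULT_TAU_P
    n_bins: int = DEFAULT_N_BINS
    top_k: int = DEFAULT_TOP_K
    ranking_criterion: str = "absolute"
    model: dict[str, Any] = field(default_factory=dict)
    training: dict[str, Any] = field(default_factory=dict)
    cv_folds: int = 5
    n_summary_sites: int = 5
    gene_lookup_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise mio.ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full pipeline; returns the artifact manifest.

    Raises with the failing stage's name in the message; validates inputs
    before any computation.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict[str, Any] = {"config": asdict(config), "artifacts": {}}
    t0 = time.time()
    try:
        # -- stage: inputs ---------------------------------------------
        if config.synthetic is not None:
            syn = dict(config.synthetic)
            syn.setdefault("seed", config.seed)
            cohort_cfg = SyntheticCohortConfig(**syn)
            matrix, metadata, truth = generate_cohort(cohort_cfg)
            mio.write_beta_matrix(matrix, out / "betas.tsv")
            mio.write_sample_metadata(metadata, out / "metadata.tsv")
            truth.manifest().to_csv(out / "ground_truth.tsv", sep="\t", index=False)
            manifest["artifacts"]["betas"] = str(out / "betas.tsv")
            manifest["artifacts"]["metadata"] = str(out / "metadata.tsv")
            manifest["artifacts"]["ground_truth"] = str(out / "ground_truth.tsv")
            log.info(
                "simulate: %d samples x %d sites", matrix.n_samples, matrix.n_sites
            )
        else:
            if not config.betas_path or not config.metadata_path:
                raise mio.ValidationError(
                    "stage inputs: need betas_path and metadata_path (or synthetic)"
                )
            for p in (config.betas_path, config.metadata_path):
                if not Path(p).exists():
                    raise mio.ValidationError(f"stage inputs: path {p!r} does not exist")
            vocab = config.tissue_vocabulary or list(mio.DEFAULT_TISSUES)
            matrix = mio.read_beta_matrix(config.betas_path)
            metadata = mio.read_sample_metadata(config.metadata_path, vocab)
            manifest["artifacts"]["betas"] = str(config.betas_path)
            manifest["artifacts"]["metadata"] = str(config.metadata_path)
            log.info("load: %d samples x %d sites", matrix.n_samples, matrix.n_sites)

        gene_lookup = (
            mio.read_gene_lookup(config.gene_lookup_path)
            if config.gene_lookup_path
            else {}
        )

        # -- stage: tissue screen --------------------------------------
        t = time.time()
        screen = screen_tissue_specific(matrix, metadata, config.tau_p, config.n_bins)
        rows = [
            {
                "site_id": r.site_id,
                "statistic": r.statistic,
                "df": r.df,
                "p_value": r.p_value,
                "selected": int(r.site_id in set(screen.selected_sites)),
            }
            for r in screen.results
        ]
        mio.write_result_table(rows, out / "tissue_sites.tsv")
        manifest["artifacts"]["tissue_sites"] = str(out / "tissue_sites.tsv")
        log.info(
            "tissue screen: %d of %d sites selected at tau_p=%g (%.1fs)",
            len(screen.selected_sites), matrix.n_sites, config.tau_p, time.time() - t,
        )
        if not screen.selected_sites:
            raise mio.ValidationError("stage tissue screen: no sites selected")

        # -- stage: per-tissue ranking + summaries + model -------------
        manifest["artifacts"]["rankings"] = {}
        manifest["artifacts"]["summaries"] = {}
        manifest["artifacts"]["models"] = {}
        manifest["artifacts"]["metrics"] = {}
        metrics_all: dict[str, Any] = {}
        for tissue in metadata.tissues_present():
            statuses = {
                metadata.status_for([s])[0] for s in metadata.select(tissue=tissue)
            }
            if statuses != {0, 1}:
                log.info("tissue %s: single status, skipping disease stages", tissue)
                continue
            t = time.time()
            ranking = rank_disease_sites(
                matrix,
                metadata,
                tissue,
                screen.selected_sites,
                top_k=config.top_k,
                criterion=config.ranking_criterion,
            )
            tag = tissue.replace(" ", "_")
            rank_rows = [
                {
                    "rank": i + 1,
                    "site_id": s,
                    "coefficient": ranking.coefficients[s],
                    "selected": int(i < len(ranking.selected_sites)),
                }
                for i, s in enumerate(ranking.site_ids_ranked)
            ]
            mio.write_result_table(rank_rows, out / f"ranking_{tag}.tsv")
            manifest["artifacts"]["rankings"][tissue] = str(out / f"ranking_{tag}.tsv")
            log.info(
                "disease ranking %s: top %d of %d candidates (%.1fs)",
                tissue, len(ranking.selected_sites), len(ranking.site_ids_ranked),
                time.time() - t,
            )

            summaries = []
            for s in ranking.selected_sites[: config.n_summary_sites]:
                sm = site_summary(matrix, metadata, tissue, s)
                row = asdict(sm)
                if gene_lookup:
                    row["gene"] = gene_lookup.get(s, "")
                summaries.append(row)
            mio.write_result_table(summaries, out / f"summary_{tag}.tsv")
            manifest["artifacts"]["summaries"][tissue] = str(out / f"summary_{tag}.tsv")

            # train on the selected panel
            t = time.time()
            panel = ranking.selected_sites
            sample_ids = metadata.select(tissue=tissue)
            sub = matrix.subset_samples(sample_ids).subset_sites(panel)
            X = sub.betas.copy()
            col_mean = np.nanmean(X, axis=0)
            nan_r, nan_c = np.where(np.isnan(X))
            X[nan_r, nan_c] = col_mean[nan_c]
            y = metadata.status_for(sample_ids)
            train_cfg = TrainConfig(**{"seed": config.seed, **config.training})
            margs = dict(config.model)
            margs["heads"] = compatible_heads(len(panel), margs.get("heads", 4))
            model, history = train_model(X, y, train_cfg, site_ids=panel, **margs)
            model.site_ids = panel
            model_dir = out / f"model_{tag}"
            model.save(model_dir)
            (model_dir / "history.json").write_text(json.dumps(history))
            manifest["artifacts"]["models"][tissue] = str(model_dir)
            log.info("train %s: %d epochs (%.1fs)", tissue,
                     len(history["train_loss"]), time.time() - t)

            # cross-validated evaluation on the same panel
            t = time.time()
            cv = crossval_evaluate(
                matrix, metadata, tissue, panel,
                model_spec="transformer", k=config.cv_folds, seed=config.seed,
                train_config=train_cfg, model_args=margs,
            )
            metrics_all[tissue] = {
                "accuracy": cv.accuracy,
                "recall": cv.recall,
                "f1": cv.f1,
                "auc": cv.auc,
                "mean_accuracy": cv.mean_accuracy,
            }
            np.savetxt(
                out / f"roc_{tag}.tsv", cv.roc_points, delimiter="\t",
                header="fpr\ttpr", comments="",
            )
            manifest["artifacts"]["metrics"][tissue] = str(out / f"roc_{tag}.tsv")
            log.info("evaluate %s: AUC %.3f (%.1fs)", tissue, cv.auc, time.time() - t)

        (out / "metrics.json").write_text(json.dumps(metrics_all, indent=2))
        manifest["artifacts"]["metrics_json"] = str(out / "metrics.json")
        manifest["elapsed_seconds"] = round(time.time() - t0, 2)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    finally:
        log.removeHandler(handler)
        handler.close()
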