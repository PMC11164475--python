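"""End-to-end orchestration: simulate/ingest -> normalize -> train ->
gradient ranking -> Shapley ranking -> intersection -> optional network and
gene-set statistics -> clinical/panel statistics.

Every run writes its artifacts with stable filenames into one output
directory together with a manifest recording the seed, the configuration,
per-stage seeds and the cohort dimensions, so a run can be re-executed from
its manifest alone.  One global seed is expanded into per-stage seeds by a
fixed counter scheme (stage k uses seed + k), keeping stages independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .downstream_stats import (
    correlation_analysis,
    correlation_frames,
    de_frame,
    differential_expression,
    regress_clinical,
    svm_biomarker,
)
from .expr_io import (
    ExpressionMatrix,
    Phenotype,
    align_phenotype,
    collapse_probes,
    read_expression_table,
    read_phenotype,
    write_expression_tsv,
    zscore_per_sample,
)
from .network_tools import (
    betweenness_centrality,
    hypergeometric_ora,
    read_edge_list,
    write_centrality_tsv,
    write_enrichment_tsv,
)
from .sensitivity_net import (
    TrainConfig,
    sensitivity_scores,
    serialize_model,
    train_model,
    write_sensitivity_tsv,
)
from .shapley_rank import average_shapley, intersect_sets, write_shapley_tsv
from .synthetic_data import ClinicalCoupling, SimulationParams, simulate_cohort

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets (stage seed = base seed + offset)
STAGE_OFFSETS = {
    "simulate": 0,
    "train": 1,
    "shapley": 2,
    "stats": 3,
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ShapleySettings:
    baseline_rule: str = "zeros"
    method: str = "auto"
    n_permutations: int = 200


@dataclass
class RunConfig:
    """Inputs, model settings and output location for one pipeline run.

    Exactly one of ``simulate`` (simulation parameters) or
    ``expression_path`` (+ ``phenotype_path``) must be supplied.
    """

    outdir: str = "genesens-run"
    seed: int = 0
    fraction: float = 0.2
    simulate: SimulationParams | None = None
    expression_path: str | None = None
    annotation_path: str | None = None
    phenotype_path: str | None = None
    edge_list_path: str | None = None
    edge_score_threshold: float | None = None
    gmt_path: str | None = None
    train: TrainConfig = field(default_factory=TrainConfig)
    shapley: ShapleySettings = field(default_factory=ShapleySettings)
    stats_top_k: int = 4  # genes carried into DE/correlation/regression/SVM

    def __post_init__(self) -> None:
        has_sim = self.simulate is not None
        has_files = self.expression_path is not None
        if has_sim == has_files:
            raise ValueError("supply exactly one of simulation params or input paths")
        if has_files and self.phenotype_path is None:
            raise ValueError("expression input requires a phenotype table")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if kwargs.get("simulate") is not None:
            sim = dict(kwargs["simulate"])
            if "block_spec" in sim:
                sim["block_spec"] = [(list(g), float(r)) for g, r in sim["block_spec"]]
            if isinstance(sim.get("clinical_coupling"), dict):
                sim["clinical_coupling"] = ClinicalCoupling(**sim["clinical_coupling"])
            kwargs["simulate"] = SimulationParams(**sim)
        if "train" in kwargs and isinstance(kwargs["train"], dict):
            kwargs["train"] = TrainConfig(**kwargs["train"])
        if "shapley" in kwargs and isinstance(kwargs["shapley"], dict):
            kwargs["shapley"] = ShapleySettings(**kwargs["shapley"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj

        return {k: convert(v) for k, v in dataclasses.asdict(self).items()}


def _load_cohort(cfg: RunConfig):
    if cfg.simulate is not None:
        params = dataclasses.replace(cfg.simulate, seed=cfg.seed + STAGE_OFFSETS["simulate"])
        return simulate_cohort(params)
    pm = read_expression_table(cfg.expression_path, annotation=cfg.annotation_path)
    ph = read_phenotype(cfg.phenotype_path)
    return pm, ph


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages; return the artifact directory.

    Any stage failure aborts with a :class:`StageError` naming the stage,
    after persisting a partial manifest.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "stage_seed_offsets": STAGE_OFFSETS,
        "config": cfg.to_dict(),
        "stages_completed": [],
    }

    def finish_stage(name: str) -> None:
        manifest["stages_completed"].append(name)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    stage = "expr_io"
    try:
        pm, ph = _load_cohort(cfg)
        em = zscore_per_sample(collapse_probes(pm))
        em, ph = align_phenotype(em, ph)
        manifest["m_genes"] = em.m
        manifest["n_samples"] = em.n
        manifest["group_counts"] = {
            g: int(sum(x == g for x in ph.group)) for g in sorted(set(ph.group))
        }
        write_expression_tsv(em, outdir / "expression_normalized.tsv")
        finish_stage(stage)

        stage = "train"
        train_cfg = dataclasses.replace(cfg.train, seed=cfg.seed + STAGE_OFFSETS["train"])
        model = train_model(em, ph, train_cfg)
        with open(outdir / "model.json", "w") as fh:
            json.dump(serialize_model(model), fh)
        finish_stage(stage)

        stage = "sensitivity"
        sens = sensitivity_scores(model, em, fraction=cfg.fraction)
        write_sensitivity_tsv(sens, outdir / "sensitivity_ranking.tsv")
        manifest["sensitivity_top5"] = sens.ranking[:5]
        finish_stage(stage)

        stage = "shapley"
        shap = average_shapley(
            model,
            em,
            baseline_rule=cfg.shapley.baseline_rule,
            fraction=cfg.fraction,
            method=cfg.shapley.method,
            n_permutations=cfg.shapley.n_permutations,
            seed=cfg.seed + STAGE_OFFSETS["shapley"],
        )
        write_shapley_tsv(shap, outdir / "shapley_ranking.tsv")
        manifest["shapley_top5"] = shap.ranking[:5]
        finish_stage(stage)

        stage = "intersect"
        intersection = intersect_sets(sens.top_set, shap.top_set)
        with open(outdir / "intersection.txt", "w") as fh:
            fh.write("\n".join(intersection) + ("\n" if intersection else ""))
        manifest["intersection_size"] = len(intersection)
        finish_stage(stage)

        if cfg.gmt_path is not None:
            stage = "ora"
            universe = set(em.gene_ids)
            query = set(intersection) & universe or set(sens.ranking[: cfg.stats_top_k])
            rows = hypergeometric_ora(query, cfg.gmt_path, universe)
            write_enrichment_tsv(rows, outdir / "enrichment.tsv")
            finish_stage(stage)

        if cfg.edge_list_path is not None:
            stage = "centrality"
            network = read_edge_list(cfg.edge_list_path, cfg.edge_score_threshold)
            write_centrality_tsv(betweenness_centrality(network), outdir / "centrality.tsv")
            finish_stage(stage)

        stage = "stats"
        focus = intersection[: cfg.stats_top_k] if len(intersection) >= 2 else sens.ranking[: cfg.stats_top_k]
        de_frame(differential_expression(em, ph, focus)).to_csv(
            outdir / "differential_expression.tsv", sep="\t", index=False
        )
        for name, frame in correlation_frames(
            correlation_analysis(em, ph, focus)
        ).items():
            frame.to_csv(outdir / f"correlation_{name}.tsv", sep="\t")
        regressions = []
        for gene in focus:
            for indicator, present in (("MMSE", ph.mmse), ("NFT", ph.nft)):
                if present is not None:
                    fit = regress_clinical(em, ph, gene, indicator)
                    regressions.append(fit.__dict__)
        if regressions:
            import pandas as pd

            pd.DataFrame(regressions).to_csv(outdir / "clinical_regression.tsv", sep="\t", index=False)
        svm = svm_biomarker(
            em, ph, focus[: max(2, min(len(focus), cfg.stats_top_k))],
            seed=cfg.seed + STAGE_OFFSETS["stats"],
        )
        with open(outdir / "svm_report.json", "w") as fh:
            json.dump(
                {
                    "panel": svm.panel,
                    "kernel": svm.kernel,
                    "train_fraction": svm.train_fraction,
                    "seed": svm.seed,
                    "test_accuracy": svm.test_accuracy,
                    "cv_accuracies": svm.cv_accuracies,
                    "decision_thresholds": svm.decision_thresholds,
                },
                fh,
                indent=2,
            )
        finish_stage(stage)
    except StageError:
        raise
    except Exception as exc:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump({**manifest, "failed_stage": stage, "error": str(exc)}, fh, indent=2, default=str)
        raise StageError(stage, exc) from exc

    logger.info("pipeline complete: %s", outdir)
    return outdir
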