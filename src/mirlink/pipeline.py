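"""End-to-end pipeline: input -> preprocess -> DE -> sSCCA -> networks -> integration.

Stage defaults follow the motivating study throughout: BH-adjusted DE at
alpha 0.01, sparse-CCA penalties 0.3 (miRNA loadings) / 0.5 (mRNA), SPACE
penalty from the quantile rule with alpha 1 recomputed from the actual
post-DE feature count, A*-lasso penalty 0.2 with a 3000-entry queue.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bayesnet import AStarLasso
from .cca import SparseCCA, standardize_columns
from .containers import ExpressionMatrix, GroupDesign
from .de import run_de
from .integrate import IntegratedNetwork, compare_networks, integrate
from .pearson import PearsonCorrelationNetwork
from .preprocess import preprocess_matrix
from .space import SpacePartialCorrelation, default_lam1
from .synth import SynthConfig, generate_dataset

logger = logging.getLogger("mirlink.pipeline")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every stage parameter of the pipeline, serializable to YAML."""

    # input: either file paths or a synthetic-data config
    mirna_path: str | None = None
    mrna_path: str | None = None
    design_path: str | None = None
    replicate_path: str | None = None
    synth: SynthConfig | None = None
    # preprocessing
    mirna_present_frac: float = 0.30
    mirna_missing_frac: float = 0.40
    mrna_missing_frac: float = 0.50
    outlier_sd: float = 3.0
    knn_k: int = 10
    filter_mode: str = "both"
    # differential expression
    de_alpha: float = 0.01
    # sparse supervised CCA
    penalty_u: float = 0.3
    penalty_v: float = 0.5
    q_frac: float = 1.0
    # SPACE ("auto" = quantile rule from the post-DE feature count)
    space_lam1: float | str = "auto"
    space_alpha: float = 1.0
    # A* lasso; the stage honors the estimator's default node cap unless
    # astar_allow_large is set (the subset state space grows as 2^p)
    astar_lambda: float = 0.2
    astar_queue: int = 3000
    astar_max_nodes: int = 25
    astar_allow_large: bool = False
    # Pearson baseline
    pearson_alpha: float = 0.01
    seed: int = 0
    outdir: str | None = None

    def to_yaml(self, path) -> None:
        d = asdict(self)
        if self.synth is not None:
            d["synth"] = asdict(self.synth)
            d["synth"]["de_effect_range"] = list(self.synth.de_effect_range)
            d["synth"]["module_size"] = list(self.synth.module_size)
            d["synth"]["baseline_mean_range"] = list(self.synth.baseline_mean_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("synth") is not None:
            s = d["synth"]
            for k in ("de_effect_range", "module_size", "baseline_mean_range"):
                if k in s and s[k] is not None:
                    s[k] = tuple(s[k])
            d["synth"] = SynthConfig(**s)
        return cls(**d)

    def __eq__(self, other) -> bool:  # dataclass eq breaks on "auto" vs float
        if not isinstance(other, PipelineConfig):
            return NotImplemented
        return asdict(self) == asdict(other)


@dataclass
class PipelineResult:
    """Fitted stage objects plus the run summary."""

    mirna: ExpressionMatrix
    mrna: ExpressionMatrix
    design: GroupDesign
    truth: object | None
    de_mirna: object
    de_mrna: object
    selected_mirna: list[str]
    selected_mrna: list[str]
    scca: SparseCCA
    space: SpacePartialCorrelation
    astar: AStarLasso | None
    pearson: PearsonCorrelationNetwork
    integrated_space: IntegratedNetwork
    integrated_astar: IntegratedNetwork | None
    comparison: dict | None
    summary: dict = field(default_factory=dict)


def _load_inputs(config: PipelineConfig):
    if config.synth is not None:
        logger.info("simulating input data (seed=%d)", config.synth.seed)
        return generate_dataset(config.synth)
    if not (config.mirna_path and config.mrna_path and config.design_path):
        raise ValueError("either synth config or all input paths must be given")
    mirna = ExpressionMatrix.read_tsv(config.mirna_path, kind="miRNA")
    mrna = ExpressionMatrix.read_tsv(config.mrna_path, kind="mRNA")
    design = GroupDesign.read_tsv(config.design_path, config.replicate_path)
    return mirna, mrna, design, None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the four-step pipeline and (optionally) write all artifacts."""
    t0 = time.time()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    current = ["input"]

    def stage(name):
        current[0] = name
        logger.info("stage: %s", name)

    try:
        stage("input")
        mirna_raw, mrna_raw, design, truth = _load_inputs(config)

        stage("preprocess")
        mirna = preprocess_matrix(
            mirna_raw, design, config.mirna_present_frac, config.mirna_missing_frac,
            config.mrna_missing_frac, config.outlier_sd, config.knn_k, config.filter_mode,
        )
        mrna = preprocess_matrix(
            mrna_raw, design, config.mirna_present_frac, config.mirna_missing_frac,
            config.mrna_missing_frac, config.outlier_sd, config.knn_k, config.filter_mode,
        )

        stage("differential expression")
        de_mi, sel_mi = run_de(mirna, design, config.de_alpha)
        de_mr, sel_mr = run_de(mrna, design, config.de_alpha)
        logger.info("selected %d miRNAs and %d mRNAs at BH-adjusted alpha=%g",
                    len(sel_mi), len(sel_mr), config.de_alpha)
        if len(sel_mi) < 2 or len(sel_mr) < 2:
            raise RuntimeError("too few DE features selected to continue")

        # samples x features, standardized, restricted to DE features
        X = standardize_columns(mirna.subset(features=sel_mi).values.T)
        Y = standardize_columns(mrna.subset(features=sel_mr).values.T)
        Xdf = pd.DataFrame(X, columns=sel_mi)
        Ydf = pd.DataFrame(Y, columns=sel_mr)
        z = design.z

        stage("sparse supervised CCA")
        scca = SparseCCA(config.penalty_u, config.penalty_v, config.q_frac).fit(Xdf, Ydf, z)
        pair = scca.canonical_pair_()
        logger.info("sSCCA selected %d miRNAs and %d mRNAs (canonical r=%.3f)",
                    len(pair.selected_x), len(pair.selected_y), pair.correlation)

        pooled = pd.concat([Xdf, Ydf], axis=1)
        n, p_pool = pooled.shape

        stage("SPACE")
        lam1 = (default_lam1(n, p_pool, config.space_alpha)
                if config.space_lam1 == "auto" else float(config.space_lam1))
        logger.info("SPACE lam1 = %.7f (n=%d, p=%d)", lam1, n, p_pool)
        space = SpacePartialCorrelation(lam1=lam1).fit(pooled)

        stage("A* lasso")
        if p_pool <= config.astar_max_nodes or config.astar_allow_large:
            astar = AStarLasso(
                lam=config.astar_lambda, queue_limit=config.astar_queue,
                max_nodes=config.astar_max_nodes,
                allow_large=config.astar_allow_large,
            ).fit(pooled)
            logger.info("A* lasso: %d edges, score %.2f, %d states expanded",
                        len(astar.edges_), astar.score_, astar.n_expanded_)
        else:
            astar = None
            logger.warning(
                "A* lasso stage skipped: %d pooled features exceed the %d-node "
                "search budget (set astar_allow_large to force the search)",
                p_pool, config.astar_max_nodes,
            )

        stage("Pearson baseline")
        pearson = PearsonCorrelationNetwork(alpha=config.pearson_alpha).fit(pooled)

        stage("integrate")
        prov = {"lam1": lam1, "de_alpha": config.de_alpha,
                "penalty_u": config.penalty_u, "penalty_v": config.penalty_v,
                "astar_lambda": config.astar_lambda, "astar_queue": config.astar_queue,
                "seed": config.seed}
        int_space = integrate(pair, space, provenance={**prov, "source": "SPACE"})
        if astar is not None:
            int_astar = integrate(pair, astar, provenance={**prov, "source": "ASTAR"})
            comparison = compare_networks(int_space, int_astar)
        else:
            int_astar = None
            comparison = None
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{current[0]}': {exc}") from exc

    summary = {
        "n_samples": int(n),
        "n_de_mirna": len(sel_mi),
        "n_de_mrna": len(sel_mr),
        "scca_selected_mirna": len(pair.selected_x),
        "scca_selected_mrna": len(pair.selected_y),
        "canonical_correlation": pair.correlation,
        "space_lam1": lam1,
        "space_n_edges": int(len(space.edges_)),
        "astar_n_edges": int(len(astar.edges_)) if astar is not None else None,
        "pearson_n_edges": int(len(pearson.edges_)),
        "integrated_space_edges": int(len(int_space.edges)),
        "integrated_astar_edges": (
            int(len(int_astar.edges)) if int_astar is not None else None
        ),
        "comparison": comparison,
        "elapsed_s": time.time() - t0,
        "seed": config.seed,
    }
    result = PipelineResult(
        mirna=mirna, mrna=mrna, design=design, truth=truth,
        de_mirna=de_mi, de_mrna=de_mr, selected_mirna=sel_mi, selected_mrna=sel_mr,
        scca=scca, space=space, astar=astar, pearson=pearson,
        integrated_space=int_space, integrated_astar=int_astar,
        comparison=comparison, summary=summary,
    )
    if outdir:
        _write_artifacts(config, result, outdir)
    logger.info("pipeline finished in %.1f s", summary["elapsed_s"])
    return result


def _write_artifacts(config: PipelineConfig, res: PipelineResult, outdir: Path) -> None:
    config.to_yaml(outdir / "config.yaml")
    res.mirna.to_tsv(outdir / "mirna_preprocessed.tsv")
    res.mrna.to_tsv(outdir / "mrna_preprocessed.tsv")
    res.design.to_tsv(outdir / "design.tsv", outdir / "replicates.tsv")
    res.de_mirna.to_tsv(outdir / "de_mirna.tsv", config.de_alpha)
    res.de_mrna.to_tsv(outdir / "de_mrna.tsv", config.de_alpha)
    res.scca.canonical_pair_().loadings_frame().to_csv(
        outdir / "scca_loadings.tsv", sep="\t", index=False
    )
    res.space.edges_.to_csv(outdir / "space_edges.tsv", sep="\t", index=False)
    if res.astar is not None:
        res.astar.edges_.to_csv(outdir / "astar_edges.tsv", sep="\t", index=False)
        with open(outdir / "astar_order.json", "w") as fh:
            json.dump({"order": [res.astar.feature_names_[i] for i in res.astar.order_]}, fh)
    res.pearson.edges_.to_csv(outdir / "pearson_edges.tsv", sep="\t", index=False)
    res.integrated_space.to_tsv(outdir / "integrated_space_edges.tsv")
    res.integrated_space.to_graphml(outdir / "integrated_space.graphml")
    if res.integrated_astar is not None:
        res.integrated_astar.to_tsv(outdir / "integrated_astar_edges.tsv")
        res.integrated_astar.to_graphml(outdir / "integrated_astar.graphml")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(res.summary, fh, indent=1, default=float)
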