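"""End-to-end orchestration: preprocess -> featurize -> train -> evaluate -> export.

A run is described by a single declarative :class:`RunConfig`; ablation
flags reproduce the four study configurations:

- baseline    — sliding-window delay matrices only,
- aggregation — neighbor smoothing + sliding window,
- adjustment  — sliding window + dual-background enhancement,
- combined    — all three (the default).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .aggregation import AggregationConfig, aggregate_expression
from .data_io import (
    ExpressionMatrix,
    PairSample,
    ReferenceNetwork,
    build_pair_samples,
    filter_gold_standard,
    filter_low_expression,
    load_expression,
    load_network,
    select_hvg,
    split_samples,
)
from .delay import WindowConfig, build_delay_matrix, default_window_config
from .enhancement import enhance
from .evaluation import EvalReport, compute_metrics, export_grn
from .model import FeaturizedPair, ModelConfig, build_model, predict, train

__all__ = ["RunConfig", "ABLATIONS", "preprocess", "featurize_pairs", "run_pipeline", "run_in_memory"]

logger = logging.getLogger(__name__)

# named ablation configurations: (skip_aggregation, skip_enhancement)
ABLATIONS: dict[str, tuple[bool, bool]] = {
    "baseline": (True, True),
    "aggregation": (False, True),
    "adjustment": (True, False),
    "combined": (False, False),
}


@dataclass
class RunConfig:
    # paths (optional when running in memory)
    expr: str | None = None
    pseudotime: str | None = None
    gold: str | None = None
    refs: list[str] = field(default_factory=list)
    workdir: str | None = None
    # preprocessing
    top_n: int = 1000
    log1p: bool = False
    seed: int = 1
    skip_low_expression_filter: bool = False
    # aggregation
    agg_k: int = 10
    similarity: str = "pearson"
    skip_aggregation: bool = False
    # window geometry (None -> solved from trajectory length)
    window: WindowConfig | None = None
    # enhancement
    combine: str = "euclidean"
    ddof: int = 0
    skip_enhancement: bool = False
    # model
    model: ModelConfig = field(default_factory=ModelConfig)
    # evaluation
    k_list: list[int] = field(default_factory=lambda: [10, 25, 50])
    alpha: float = 0.05

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "model" in raw and isinstance(raw["model"], dict):
            raw["model"] = ModelConfig(**raw["model"])
        if "window" in raw and isinstance(raw["window"], dict):
            raw["window"] = WindowConfig(**raw["window"])
        return cls(**raw)


def preprocess(
    expr: ExpressionMatrix, gold: ReferenceNetwork, cfg: RunConfig
) -> tuple[ExpressionMatrix, ReferenceNetwork, list[PairSample]]:
    """Steps 2-5: expression QC, HVG selection, gold filtering, pair sampling."""
    if not cfg.skip_low_expression_filter:
        expr = filter_low_expression(expr)
    top_n = min(cfg.top_n, expr.n_genes)
    if top_n < cfg.top_n:
        logger.info("top_n capped at available gene count %d", top_n)
    expr = select_hvg(expr, top_n, log1p=cfg.log1p)
    gold = filter_gold_standard(gold, expr)
    samples = build_pair_samples(gold, expr, seed=cfg.seed)
    return expr, gold, samples


def featurize_pairs(
    expr: ExpressionMatrix,
    samples: list[PairSample],
    window: WindowConfig,
    cfg: RunConfig,
) -> list[FeaturizedPair]:
    """Delay matrices (optionally on smoothed expression, optionally enhanced)."""
    work = expr
    if not cfg.skip_aggregation:
        agg = AggregationConfig(k=min(cfg.agg_k, expr.n_genes - 1), similarity=cfg.similarity)
        work = aggregate_expression(expr, agg)
    index = {g: i for i, g in enumerate(work.gene_ids)}
    out = []
    for s in samples:
        M = build_delay_matrix(
            work.values[index[s.tf_id]], work.values[index[s.target_id]], window,
            tf_id=s.tf_id, target_id=s.target_id,
        )
        if cfg.skip_enhancement:
            mat = M.values
        else:
            mat = enhance(M, combine=cfg.combine, ddof=cfg.ddof).values
        out.append(FeaturizedPair(s.tf_id, s.target_id, s.label, mat))
    return out


def run_in_memory(
    expr: ExpressionMatrix,
    gold: ReferenceNetwork,
    cfg: RunConfig,
    refs: list[ReferenceNetwork] | None = None,
    cell_order: np.ndarray | None = None,
) -> tuple[EvalReport, dict]:
    """Execute the full pipeline on in-memory objects.

    ``cell_order`` optionally permutes the cells before featurization (used
    by the pseudotime-perturbation analysis).  Returns the held-out test
    report and a dict of artifacts (scores table, exported network, model,
    window geometry, splits).
    """
    expr, gold, samples = preprocess(expr, gold, cfg)
    if cell_order is not None:
        expr = ExpressionMatrix(
            gene_ids=list(expr.gene_ids),
            cell_ids=[expr.cell_ids[i] for i in cell_order],
            values=expr.values[:, cell_order],
            pseudotime=None,
        )
    window = cfg.window or default_window_config(expr.n_cells)
    train_s, val_s, test_s = split_samples(samples, seed=cfg.seed)
    feats = {
        id(s): f
        for s, f in zip(samples, featurize_pairs(expr, samples, window, cfg))
    }
    tr = [feats[id(s)] for s in train_s]
    va = [feats[id(s)] for s in val_s]
    te = [feats[id(s)] for s in test_s]

    model_cfg = dataclasses.replace(cfg.model, seed=cfg.model.seed or cfg.seed)
    model = build_model(model_cfg, (window.p, window.q))
    model = train(model, tr, va, model_cfg)

    test_scores = predict(model, [f.matrix for f in te])
    report = compute_metrics(test_scores, [f.label for f in te], k_list=cfg.k_list, alpha=cfg.alpha)

    all_feats = [feats[id(s)] for s in samples]
    all_scores = predict(model, [f.matrix for f in all_feats])
    scored = [(f.tf_id, f.target_id, s) for f, s in zip(all_feats, all_scores)]
    grn = export_grn(scored, gold, refs=refs)
    scores_df = pd.DataFrame(
        {
            "tf": [f.tf_id for f in all_feats],
            "target": [f.target_id for f in all_feats],
            "label": [f.label for f in all_feats],
            "score": all_scores,
        }
    )
    artifacts = {
        "model": model,
        "window": window,
        "scores": scores_df,
        "grn": grn,
        "splits": {"train": train_s, "val": val_s, "test": test_s},
        "gold": gold,
    }
    return report, artifacts


def run_pipeline(cfg: RunConfig) -> EvalReport:
    """Load inputs from ``cfg`` paths, run the pipeline, write artifacts."""
    if cfg.expr is None or cfg.gold is None:
        raise ValueError("run_pipeline requires expr and gold paths; "
                         "use run_in_memory for object inputs")
    expr = load_expression(cfg.expr, pseudotime_path=cfg.pseudotime)
    gold = load_network(cfg.gold, label="gold")
    refs = [load_network(p, label=os.path.splitext(os.path.basename(p))[0]) for p in cfg.refs]
    report, artifacts = run_in_memory(expr, gold, cfg, refs=refs)

    if cfg.workdir:
        os.makedirs(cfg.workdir, exist_ok=True)
        with open(os.path.join(cfg.workdir, "config.yaml"), "w") as fh:
            resolved = cfg.resolved()
            yaml.safe_dump(resolved, fh, sort_keys=False)
        with open(os.path.join(cfg.workdir, "metrics.json"), "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        artifacts["scores"].to_csv(os.path.join(cfg.workdir, "scores.tsv"), sep="\t", index=False)
        artifacts["grn"].to_csv(os.path.join(cfg.workdir, "grn.tsv"), sep="\t", index=False)
        hist = pd.DataFrame(artifacts["model"].history)
        hist.to_csv(os.path.join(cfg.workdir, "training_history.tsv"), sep="\t", index=False)
        logger.info("artifacts written to %s", cfg.workdir)
    return report
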