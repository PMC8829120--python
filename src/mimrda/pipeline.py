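"""End-to-end orchestration: read -> DE -> ORA -> combine -> rank -> write.

``run_pipeline`` is the in-memory core (expression matrices and interaction
table in, ranked score table + run report out); ``run_mimrda`` wraps it with
file IO and a JSON run report. Identical config and seed produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import diffexpr, global_score, target_ora
from .io_formats import (
    ExpressionMatrix,
    InteractionTable,
    MimrdaError,
    SampleMetadata,
    read_expression,
    read_interactions,
    read_metadata,
    write_scores,
)

logger = logging.getLogger("mimrda")


@dataclass
class RunConfig:
    """All knobs of one pipeline run."""

    mrna_expression: str = ""
    mirna_expression: str = ""
    metadata: str = ""
    interactions: str = ""
    output_dir: str = "mimrda_out"
    alpha_mrna: float = 0.01
    alpha_mirna: float = 0.01
    universe_mode: str = "measured_intersection"
    min_targets: int = 1
    prefilter_de_mirnas: bool = False
    top_k_report: int = 20
    log2_transform: bool = False
    ordinary_t: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_mrna", "alpha_mirna"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise MimrdaError(f"{name} must lie in (0, 1), got {a}")


class StageError(MimrdaError):
    """An error raised by a pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except MimrdaError as exc:
        raise StageError(name, exc) from exc


def run_pipeline(mrna_expr: ExpressionMatrix, mirna_expr: ExpressionMatrix,
                 meta: SampleMetadata, interactions: InteractionTable,
                 config: RunConfig | None = None,
                 ) -> tuple[pd.DataFrame, dict]:
    """Execute the scoring workflow on in-memory objects.

    Returns (scores, report): the ranked score table and a report dict
    echoing N (dataset-wide DE_mRNA count), M, k and per-stage counts.
    """
    cfg = config or RunConfig()
    mrna_de = _stage("diffexpr_mrna", diffexpr.run_de, mrna_expr, meta,
                     alpha=cfg.alpha_mrna, ordinary_t=cfg.ordinary_t)
    mirna_de = _stage("diffexpr_mirna", diffexpr.run_de, mirna_expr, meta,
                      alpha=cfg.alpha_mirna, ordinary_t=cfg.ordinary_t)
    de_mrnas = diffexpr.select_de(mrna_de, cfg.alpha_mrna)
    universe = _stage("universe", target_ora.build_universe, interactions,
                      set(mrna_expr.feature_ids), cfg.universe_mode)
    ora = _stage("ora", target_ora.run_ora, interactions, de_mrnas, universe,
                 n_total_de=len(de_mrnas), min_targets=cfg.min_targets)
    scores = _stage("global_score", global_score.score_all, mirna_de, ora,
                    prefilter_de_mirnas=cfg.prefilter_de_mirnas,
                    alpha_mirna=cfg.alpha_mirna)
    report = {
        "config": asdict(cfg),
        "n_mrnas": len(mrna_expr.feature_ids),
        "n_mirnas": len(mirna_expr.feature_ids),
        "n_samples": len(meta.sample_ids),
        "n_interactions": len(interactions),
        "N": len(de_mrnas),
        "M": len(universe),
        "k": int(ora["k"].iloc[0]) if len(ora) else 0,
        "n_de_mirnas": int(mirna_de["is_de"].sum()),
        "n_scored": len(scores),
        "top_k": scores["mirna_id"].head(cfg.top_k_report).tolist(),
    }
    return scores, report


def run_mimrda(config: RunConfig) -> Path:
    """File-based pipeline run; returns the output directory.

    Writes ``scores.tsv`` (ranked) and ``report.json`` under
    ``config.output_dir``.
    """
    cfg = config
    mrna = _stage("read_mrna", read_expression, cfg.mrna_expression, "mRNA",
                  log2_transform=cfg.log2_transform)
    mirna = _stage("read_mirna", read_expression, cfg.mirna_expression,
                   "miRNA", log2_transform=cfg.log2_transform)
    meta = _stage("read_metadata", read_metadata, cfg.metadata)
    inter = _stage("read_interactions", read_interactions, cfg.interactions)
    scores, report = run_pipeline(mrna, mirna, meta, inter, cfg)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_scores(scores, out / "scores.tsv")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("wrote %s (N=%d, M=%d, k=%d, %d miRNAs scored)",
                out / "scores.tsv", report["N"], report["M"], report["k"],
                report["n_scored"])
    return out
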