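"""End-to-end orchestration: simulate -> rank -> windows -> classify ->
stability -> cluster -> coherence.

A run is described by a :class:`RunConfig` (typically loaded from YAML),
executed into an output directory of plain CSV/JSON artifacts plus a
manifest recording every stage's parameters, derived seed, status and output
files. Stages communicate only through serialized artifacts; independent
stages continue when one fails. A single master seed governs all
randomness, with fixed per-stage offsets.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import bhi, correlation_distance_matrix, hierarchical_cluster, leaf_order
from .coherence import coherence_curve, mutual_coherence
from .data import (ExpressionMatrix, PhenotypeTable, read_expression,
                   read_phenotypes, train_test_split, write_expression,
                   write_phenotypes)
from .ranking import (build_windows, evaluate_windows, rank_genes,
                      resample_prediction, resample_stability, window_table)
from .registry import METHODS
from .simulate import SyntheticConfig, generate_study

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis", "STAGES"]

STAGES = ("simulate", "rank", "windows", "classify", "stability",
          "cluster", "coherence")

# fixed, documented per-stage seed offsets from the master seed
SEED_OFFSETS = {"simulate": 0, "split": 1, "classify": 2, "stability": 3,
                "resample": 4}


@dataclass
class RunConfig:
    """Parameters of a full run; either synthetic or file-based input."""

    out_dir: str = "genestab_run"
    seed: int = 0
    synthetic: dict | None = None          # SyntheticConfig overrides
    expression_path: str | None = None
    phenotype_path: str | None = None
    n_train: int = 78
    n_ranked: int = 230
    ranking_method: str = "correlation"
    window_width: int = 70
    window_step: int = 5
    methods: tuple[str, ...] = ("vantveer", "dlda", "adaboost")
    method_kwargs: dict = field(default_factory=dict)
    subsample_size: int = 50
    n_resamples: int = 100
    top_k: int = 70
    stability_classifier: str = "dlda"
    cluster_k: int | None = None
    cluster_categories: tuple[str, ...] = ("y", "er", "pr")
    coherence_mode: str = "raw_cosine"
    curve_points: int = 200

    def __post_init__(self) -> None:
        if self.synthetic is None and (
            self.expression_path is None or self.phenotype_path is None
        ):
            raise ValueError(
                "config must provide either a synthetic block or both "
                "expression_path and phenotype_path"
            )
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "methods" in raw:
            raw = {**raw, "methods": tuple(raw["methods"])}
        if "cluster_categories" in raw:
            raw = {**raw, "cluster_categories": tuple(raw["cluster_categories"])}
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        return (self.seed + SEED_OFFSETS[stage]) % (2**31)


def _load_or_simulate(config: RunConfig, out: Path):
    if config.synthetic is not None:
        syn = SyntheticConfig(**{**config.synthetic,
                                 "seed": config.stage_seed("simulate")})
        study = generate_study(syn)
        expr, phen = study.expression, study.phenotypes
        write_expression(expr, out / "expression.tsv")
        write_phenotypes(phen, out / "phenotypes.tsv")
        truth = pd.DataFrame({
            "gene_id": expr.gene_ids,
            "informative": [g in study.informative_gene_ids for g in expr.gene_ids],
            "block": [study.block_assignment[g] for g in expr.gene_ids],
        })
        truth.to_csv(out / "truth.csv", index=False)
        files = ["expression.tsv", "phenotypes.tsv", "truth.csv"]
    else:
        expr = read_expression(config.expression_path)
        phen = read_phenotypes(config.phenotype_path)
        files = []
    return expr, phen, files


def run_full_analysis(config: RunConfig) -> Path:
    """Execute every stage, writing artifacts and a manifest to
    ``config.out_dir``; returns the output directory path."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("genestab")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "seed_offsets": SEED_OFFSETS,
        "stages": {},
    }

    def run_stage(name, fn):
        t0 = time.perf_counter()
        entry = {"status": "ok", "files": [], "wall_time_s": None}
        try:
            entry["files"] = fn() or []
        except Exception as exc:  # noqa: BLE001 - recorded per contract
            entry["status"] = "failed"
            entry["error"] = f"{type(exc).__name__}: {exc}"
            logger.warning("stage %s failed: %s", name, entry["error"])
        entry["wall_time_s"] = round(time.perf_counter() - t0, 3)
        manifest["stages"][name] = entry
        logger.info("stage %s: %s (%.3fs)", name, entry["status"],
                    entry["wall_time_s"])

    state: dict = {}

    def stage_simulate():
        expr, phen, files = _load_or_simulate(config, out)
        phen.check_paired(expr)
        (train, test) = train_test_split(expr, phen, config.n_train,
                                         config.stage_seed("split"))
        state.update(expr=expr, phen=phen, train=train, test=test)
        return files

    def stage_rank():
        tr_expr, tr_phen = state["train"]
        ranking = rank_genes(tr_expr, tr_phen, config.ranking_method)
        n_ranked = min(config.n_ranked, len(ranking.gene_ids))
        ranking.gene_ids = ranking.gene_ids[:n_ranked]
        state["ranking"] = ranking
        df = pd.DataFrame({
            "rank": np.arange(1, n_ranked + 1),
            "gene_id": ranking.gene_ids,
            "score": ranking.scores[ranking.gene_ids].to_numpy(),
        })
        df.to_csv(out / "ranking.csv", index=False)
        return ["ranking.csv"]

    def stage_windows():
        family = build_windows(state["ranking"], config.window_width,
                               config.window_step)
        evs = evaluate_windows(family, state["ranking"], state["train"],
                               state["test"], methods=config.methods,
                               method_kwargs=config.method_kwargs)
        window_table(evs).to_csv(out / "windows.csv", index=False)
        state["family"] = family
        return ["windows.csv"]

    def stage_classify():
        tr_expr, tr_phen = state["train"]
        te_expr, te_phen = state["test"]
        genes = state["ranking"].gene_ids[:config.window_width]
        rows, score_rows = [], []
        for m in config.methods:
            kw = dict(config.method_kwargs.get(m, {}))
            if m == "aucboost":
                kw.setdefault("seed", config.stage_seed("classify"))
            res = METHODS[m](tr_expr, tr_phen, genes=genes).fit(**kw)
            for tag, expr_, phen_ in (("train", tr_expr, tr_phen),
                                      ("test", te_expr, te_phen)):
                rep = (res.train_report if tag == "train"
                       else res.evaluate(expr_, phen_, tag))
                rows.append({"method": m, "split": tag, "auc": rep.auc,
                             "error_rate": rep.error_rate,
                             "threshold": res.threshold})
                s = res.score(expr_)
                pred = np.where(s >= res.threshold, 1, -1)
                y = phen_.labels_for(expr_.sample_ids)
                score_rows.extend(
                    {"method": m, "split": tag, "sample_id": sid,
                     "score": float(si), "predicted": int(pi), "y": int(yi)}
                    for sid, si, pi, yi in zip(expr_.sample_ids, s, pred, y))
        pd.DataFrame(rows).to_csv(out / "classify_metrics.csv", index=False)
        pd.DataFrame(score_rows).to_csv(out / "classify_scores.csv", index=False)
        return ["classify_metrics.csv", "classify_scores.csv"]

    def stage_stability():
        tr_expr, tr_phen = state["train"]
        rep = resample_stability(
            tr_expr, tr_phen, config.subsample_size, config.n_resamples,
            config.top_k, config.ranking_method,
            seed=config.stage_seed("stability"))
        rep.inclusion_rate.rename("inclusion_rate").to_csv(
            out / "stability.csv", index_label="gene_id")
        metrics = resample_prediction(
            tr_expr, tr_phen, config.subsample_size, config.n_resamples,
            config.top_k, config.ranking_method, config.stability_classifier,
            seed=config.stage_seed("resample"))
        pd.DataFrame([{"resample": r.dataset_tag, "auc": r.auc,
                       "error_rate": r.error_rate} for r in metrics]
                     ).to_csv(out / "resample_metrics.csv", index=False)
        return ["stability.csv", "resample_metrics.csv"]

    def stage_cluster():
        tr_expr, tr_phen = state["train"]
        genes = state["ranking"].gene_ids[:config.window_width]
        sub = tr_expr.subset_genes(genes)
        dist_s = correlation_distance_matrix(sub, axis="samples")
        dist_g = correlation_distance_matrix(sub, axis="genes")
        rows = []
        cats = {"y": tr_phen.y, "er": tr_phen.er, "pr": tr_phen.pr}
        n_labels = {c: len(set(v.dropna())) for c, v in cats.items() if v is not None}
        K = config.cluster_k or max(n_labels.values(), default=2)
        assign = hierarchical_cluster(dist_s, K)
        assign.labels.rename("cluster").to_csv(out / "clusters.csv",
                                               index_label="sample_id")
        for cat in config.cluster_categories:
            series = cats.get(cat)
            if series is None:
                logger.warning("category %s absent; BHI skipped", cat)
                continue
            res = bhi(assign, series, category_name=cat)
            rows.append({"category": cat, "K": res.K, "bhi": res.value})
        pd.DataFrame(rows).to_csv(out / "bhi.csv", index=False)
        pd.Series(leaf_order(dist_s), name="sample_id").to_csv(
            out / "leaf_order_samples.csv", index=False)
        pd.Series(leaf_order(dist_g), name="gene_id").to_csv(
            out / "leaf_order_genes.csv", index=False)
        return ["clusters.csv", "bhi.csv", "leaf_order_samples.csv",
                "leaf_order_genes.csv"]

    def stage_coherence():
        tr_expr, _ = state["train"]
        genes = state["ranking"].gene_ids[:config.window_width]
        rep = mutual_coherence(tr_expr, genes=genes, mode=config.coherence_mode)
        payload = {"mu": rep.mu, "argmax_pair": list(rep.argmax_pair),
                   "sparsity_bound": rep.sparsity_bound, "mode": rep.mode,
                   "n_pairs": rep.n_pairs}
        (out / "coherence.json").write_text(json.dumps(payload, indent=2))
        curve = coherence_curve(rep, config.curve_points)
        pd.DataFrame(curve, columns=["quantile", "abs_corr"]).to_csv(
            out / "curve.csv", index=False)
        return ["coherence.json", "curve.csv"]

    fns = {"simulate": stage_simulate, "rank": stage_rank,
           "windows": stage_windows, "classify": stage_classify,
           "stability": stage_stability, "cluster": stage_cluster,
           "coherence": stage_coherence}
    try:
        needs_ranking = {"windows", "classify", "cluster", "coherence"}
        for name in STAGES:
            if name != "simulate" and "train" not in state:
                manifest["stages"][name] = {"status": "skipped",
                                            "error": "no input data"}
                continue
            if name in needs_ranking and "ranking" not in state:
                manifest["stages"][name] = {"status": "skipped",
                                            "error": "no ranking"}
                continue
            run_stage(name, fns[name])
    finally:
        root.removeHandler(handler)
        handler.close()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
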