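"""End-to-end pipeline: counts → network → eigengenes → classifier reports.

A :class:`PipelineConfig` collects the input paths and every stage
parameter; :func:`run_pipeline` executes filter → normalize →
residualize → (power pick or override) → network → eigengenes →
association → classifier fit/apply and writes five outputs (module TSV,
eigengene TSV, classification JSON, performance JSON, edge TSV).  The
full parameter block and the global seed are echoed into the log and the
report bundle so runs are reproducible from their outputs alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .classify import EigengeneClassifier
from .dataset import ExpressionDataset
from .modules import compute_eigengenes, module_trait_association
from .network import (
    build_adjacency,
    cluster_and_cut,
    compute_tom,
    export_top_edges,
    merge_close_modules,
    pick_soft_threshold,
)
from .normalize import cqn_like_normalize, filter_zero_genes, log2_fpkm, regress_covariates

log = logging.getLogger("coexsig")


@dataclass
class PipelineConfig:
    counts: str
    annotation: str
    metadata: str
    outdir: str = "coexsig_out"
    # normalization
    covariates: tuple[str, ...] = ("sex", "batch")
    # network
    power: int | None = 4          # explicit override; None = pick by scale-free fit
    min_module_size: int = 50
    deep_split: int = 2
    merge_cut_height: float | None = None
    # classifier
    alpha: float = 0.05
    rule: str = "single"
    modules: tuple | None = None   # default: disease-associated modules
    level: str = "individual"
    # edge export
    n_edges: int = 600
    # misc
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in (self.counts, self.annotation, self.metadata):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if not 0 <= self.deep_split <= 4:
            raise ValueError("deep_split must be in 0..4")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.rule not in ("single", "or_combination", "tree"):
            raise ValueError("rule must be single, or_combination or tree")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the report bundle (paths + objects)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = asdict(config)
    log.info("pipeline parameters: %s", json.dumps(params, default=str))

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    ds = _stage("read", cio.read_dataset, config.counts, config.annotation, config.metadata)
    ds = _stage("filter_zero_genes", filter_zero_genes, ds)
    ds = _stage("log2_fpkm", log2_fpkm, ds)
    ds = _stage("cqn_like_normalize", cqn_like_normalize, ds)
    ds = _stage("regress_covariates", regress_covariates, ds, config.covariates)

    if config.power is None:
        _, power = _stage("pick_soft_threshold", pick_soft_threshold, ds.values)
        if power is None:
            raise RuntimeError("pipeline stage 'pick_soft_threshold' failed: "
                               "no power reaches the scale-free target; set an override")
    else:
        power = int(config.power)
    log.info("soft threshold power: %d", power)

    adj = _stage("build_adjacency", build_adjacency, ds.values, power)
    tom = _stage("compute_tom", compute_tom, adj)
    _, labels = _stage(
        "cluster_and_cut", cluster_and_cut, tom, config.min_module_size, config.deep_split,
        expr=ds.values,
    )
    if config.merge_cut_height is not None:
        labels = _stage(
            "merge_close_modules", merge_close_modules, ds.values, labels,
            config.merge_cut_height,
        )

    eig = _stage("compute_eigengenes", compute_eigengenes, ds.values, labels)
    train = ds.samples["status"].isin(["case", "control"])
    assoc = _stage(
        "module_trait_association",
        module_trait_association,
        eig.values.loc[train],
        ds.samples.loc[train, "status"],
    )
    disease_modules = list(assoc.index[assoc["disease_associated"]])
    log.info("disease-associated modules: %s", disease_modules)

    chosen = list(config.modules) if config.modules else disease_modules
    if not chosen:
        raise RuntimeError("pipeline stage 'classifier' failed: no disease-associated modules")
    if config.rule == "single" and len(chosen) > 1:
        # pick the best single module by training specificity then sensitivity
        from .classify import search_combinations
        table = search_combinations(eig.values, ds.samples["status"], chosen, max_k=1,
                                    alpha=config.alpha)
        chosen = list(table.iloc[0]["modules"])
    model = EigengeneClassifier(
        eig, ds.samples["status"], disease_modules=chosen,
        family_id=ds.samples["family_id"], alpha=config.alpha,
    )
    results = _stage("classifier_fit", model.fit, config.rule, chosen)
    classification = results.classify()
    perf = results.performance(level=config.level)

    # outputs -----------------------------------------------------------
    module_tsv = outdir / "modules.tsv"
    pd.DataFrame({"gene_id": ds.values.index, "module_id": labels}).to_csv(
        module_tsv, sep="\t", index=False
    )
    eig_tsv = outdir / "eigengenes.tsv"
    eig.values.rename_axis("sample_id").to_csv(eig_tsv, sep="\t")

    cls_json = outdir / "classification.json"
    cls_payload = {
        "parameters": params,
        "power": power,
        "disease_associated_modules": [int(m) for m in disease_modules],
        "classifier_modules": [int(m) for m in chosen],
        "samples": {
            str(s): {
                "call": bool(classification.sample_table.loc[s, "call"]),
                "p": {
                    str(m): float(classification.sample_table.loc[s, f"p_{m}"])
                    for m in chosen
                },
            }
            for s in classification.sample_table.index
        },
        "families": {str(f): bool(c) for f, c in classification.family_calls.items()},
    }
    cls_json.write_text(json.dumps(cls_payload, indent=1))

    perf_json = outdir / "performance.json"
    perf_json.write_text(json.dumps({"parameters": params, **perf.to_dict()}, indent=1))

    best_module = int(chosen[0])
    edges = export_top_edges(tom, ds.values.index, labels, best_module, config.n_edges)
    edge_tsv = outdir / "edges.tsv"
    edges.to_csv(edge_tsv, sep="\t", index=False)

    return {
        "paths": {
            "modules": module_tsv,
            "eigengenes": eig_tsv,
            "classification": cls_json,
            "performance": perf_json,
            "edges": edge_tsv,
        },
        "power": power,
        "labels": labels,
        "eigengenes": eig,
        "association": assoc,
        "classifier": results,
        "classification": classification,
        "performance": perf,
    }
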