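"""Orchestration of the end-to-end demo analyses.

Two entry points: :func:`run_derivation_pipeline` chains
simulate -> QC -> normalise -> per-line marker tests -> signature
aggregation -> scoring -> classification -> metrics, and
:func:`run_calcium_pipeline` chains the calcium simulation through the
coactivity graph with its recovery metrics.  Both are deterministic given a
config and write machine-readable JSON reports.

A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence.spawn`` so that toggling one stage leaves the
others' draws unchanged.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .calcium import CoactivityParams, build_coactivity_graph
from .core_data import QCThresholds, lognormalize, qc_filter_fixed, qc_filter_mad
from .differential import aggregate_sc_signature, rank_sum_markers
from .scoring import (
    ModuleScoreParams,
    confusion_metrics,
    connectivity_score,
    predict_connectivity,
    random_control_metrics,
)
from .synthetic import CaSimConfig, ScSimConfig, simulate_calcium_recording, simulate_sc_experiment


@dataclass
class PipelineConfig:
    seed: int = 0
    run_derivation: bool = True
    run_calcium: bool = True
    run_random_control: bool = False   # 100 scored random signatures: slow, opt-in
    sc: dict = field(default_factory=dict)        # ScSimConfig overrides
    ca: dict = field(default_factory=dict)        # CaSimConfig overrides
    score: dict = field(default_factory=dict)     # ModuleScoreParams overrides
    coactivity: dict = field(default_factory=dict)  # CoactivityParams overrides


def _stage_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31) for s in
            np.random.SeedSequence(seed).spawn(n)]


def run_derivation_pipeline(cfg: PipelineConfig) -> dict:
    """Signature derivation and classification on planted synthetic data."""
    seeds = _stage_seeds(cfg.seed, 3)
    sc_cfg = ScSimConfig(**{"seed": seeds[0], **cfg.sc})
    cm, truth = simulate_sc_experiment(sc_cfg)

    cm, removed = qc_filter_fixed(cm, QCThresholds())
    keep = qc_filter_mad(cm.cell_totals(), QCThresholds().n_mads)
    cm = cm.subset_cells(keep)
    nm = lognormalize(cm)

    tables = []
    for line in sorted(nm.cell_meta["line_id"].unique()):
        in_line = nm.cell_meta["line_id"] == line
        a = (in_line & (nm.cell_meta["group_label"] == "SR101high")).to_numpy()
        b = (in_line & (nm.cell_meta["group_label"] == "SR101low")).to_numpy()
        tables.append(rank_sum_markers(nm, a, b))
    sig = aggregate_sc_signature(tables)

    params = ModuleScoreParams(**{"seed": seeds[1], **cfg.score})
    cs = connectivity_score(nm, sig, params)
    pred = predict_connectivity(cs)
    tru = nm.cell_meta["group_label"].map({"SR101high": "high", "SR101low": "low"})
    metrics = confusion_metrics(pred, tru)

    up_planted, down_planted = truth.up_genes, truth.down_genes
    jacc = len(sig.genes & (up_planted | down_planted)) / max(
        len(sig.genes | up_planted | down_planted), 1)

    report = {
        "stage": "derivation",
        "qc_removed": removed,
        "n_cells": cm.n_cells,
        "signature": {"n_up": len(sig.up), "n_down": len(sig.down)},
        "jaccard_vs_planted": jacc,
        "metrics": metrics.as_dict(),
        "confusion": {"tp": metrics.tp, "fn": metrics.fn,
                      "fp": metrics.fp, "tn": metrics.tn},
    }
    if cfg.run_random_control:
        report["random_control"] = random_control_metrics(
            nm, tru, sizes=(len(sig.up) or 40, len(sig.down) or 31),
            n_sets=100, seed=seeds[2], params=params,
        )
    return report


def run_calcium_pipeline(cfg: PipelineConfig) -> dict:
    """Coactivity-graph recovery on a simulated recording."""
    seeds = _stage_seeds(cfg.seed, 3)
    ca_cfg = CaSimConfig(**{"seed": seeds[0], **cfg.ca})
    rec = simulate_calcium_recording(ca_cfg)
    params = CoactivityParams(**{"seed": seeds[1], **cfg.coactivity})
    result = build_coactivity_graph(rec, params)

    true_edges = {tuple(sorted(e)) for e in rec.true_edges}
    found = {tuple(sorted(e)) for e in result.edges()}
    tp = len(true_edges & found)
    recall = tp / len(true_edges) if true_edges else float("nan")
    precision = tp / len(found) if found else float("nan")
    return {
        "stage": "calcium",
        "n_cells": rec.n_cells,
        "n_active": int(result.active.sum()),
        "threshold": result.threshold,
        "n_null": int(result.null_sample.size),
        "n_true_edges": len(true_edges),
        "n_coactive_edges": len(found),
        "edge_recall": recall,
        "edge_precision": precision,
    }


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run the enabled stages and assemble a versioned report."""
    cfg_dict = asdict(cfg)
    report = {
        "tool_version": __version__,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()[:16],
        "seed": cfg.seed,
        "stages": {},
    }
    if cfg.run_derivation:
        report["stages"]["derivation"] = run_derivation_pipeline(cfg)
    if cfg.run_calcium:
        report["stages"]["calcium"] = run_calcium_pipeline(cfg)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
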