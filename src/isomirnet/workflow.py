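"""End-to-end orchestration: simulate -> call -> dataset -> train -> interpret.

Chains every stage of the package on one :class:`RunConfig`, writing all
intermediate files with stable names plus a machine-readable run manifest
(package version, seeds, and the sample counts at each filter stage).
Intended for synthetic experiments and smoke runs; real analyses usually
drive the stages individually.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as ionet
from .chimera import classify_interactions, run_pipeline
from .config import RunConfig
from .dataset import build_pairs, split
from .evaluate import evaluate_predictions
from .interpret import extract_kernel_motifs, perturbation_scan
from .isomir import type_counts_from_calls, type_enrichment
from .model import build_model
from .simulate import simulate_dataset

logger = logging.getLogger(__name__)


def run_end_to_end(
    config: RunConfig,
    outdir: str | Path | None = None,
    epochs: int | None = None,
) -> dict:
    """Run all stages; returns the manifest dict (also written as JSON)."""
    cfg = config.with_derived_seeds()
    outdir = Path(outdir if outdir is not None else cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": {
            "simulation": cfg.simulation.seed,
            "negative": cfg.negative.rng_seed,
            "model": cfg.model.seed,
        },
        "counts": {},
    }
    stage = "simulate"
    try:
        sim = simulate_dataset(cfg.simulation)
        sim.write(outdir, with_hits=True)
        manifest["counts"]["reads_in"] = len(sim.reads)
        manifest["counts"]["pairs_planted"] = len(sim.pairs)

        stage = "pipeline"
        mirna_hits, tx_hits = sim.alignment_hits()
        result = run_pipeline(sim.reads, sim.mirnas, mirna_hits, tx_hits, cfg.pipeline)
        ionet.write_table(result.interactions, outdir / "interactions.tsv")
        manifest["counts"].update(result.stage_counts)

        stage = "classify-isomirs"
        calls = classify_interactions(result.interactions, sim.mirnas)
        ionet.write_table(calls, outdir / "isomir_calls.tsv")
        manifest["counts"]["isomir_calls"] = len(calls)

        stage = "enrich-types"
        if len(calls):
            enrichment = type_enrichment(type_counts_from_calls(calls))
            ionet.write_table(enrichment, outdir / "enrichment.tsv")

        stage = "build-dataset"
        pairs = build_pairs(
            result.interactions, sim.transcripts, sim.mirnas,
            sim.utr_table, cfg.negative,
        )
        ionet.write_table(pairs, outdir / "pairs.tsv")
        manifest["counts"]["pairs_pos"] = int((pairs["label"] == 1).sum())
        manifest["counts"]["pairs_neg"] = int((pairs["label"] == 0).sum())

        stage = "train"
        train_pairs, test_pairs = split(pairs, seed=cfg.seed)
        predictor = build_model(cfg.model)
        if len(train_pairs) and train_pairs["label"].nunique() >= 1:
            predictor.fit(train_pairs, epochs=epochs)
        predictor.save(outdir / "model.json")

        stage = "evaluate"
        if len(test_pairs) and test_pairs["label"].nunique() == 2:
            prob = predictor.predict_proba(test_pairs)
            report = evaluate_predictions(
                test_pairs["label"].to_numpy(), prob, cfg.model.decision_threshold
            )
            manifest["metrics"] = report.__dict__
            (outdir / "metrics.json").write_text(json.dumps(report.__dict__, indent=2))

        stage = "interpret"
        motifs = extract_kernel_motifs(predictor)
        kernel_rows = [{
            "branch": m.branch, "kernel_index": m.kernel_index,
            "informative": m.informative,
        } for m in motifs]
        ionet.write_table(pd.DataFrame(kernel_rows), outdir / "kernels.tsv")
        if len(test_pairs):
            sample = test_pairs.head(20).reset_index(drop=True)
            profiles = perturbation_scan(predictor, sample)
            ionet.write_table(profiles, outdir / "perturbation.tsv")
    except Exception as exc:
        snapshot = outdir / "failed_stage.json"
        snapshot.write_text(json.dumps({"stage": stage, "error": str(exc)}))
        raise RuntimeError(f"stage {stage!r} failed (snapshot: {snapshot})") from exc

    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
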