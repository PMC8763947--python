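"""End-to-end orchestration: simulate -> normalize -> classify -> enrich -> cluster -> respond.

A single YAML config (seed, stage toggles, per-stage parameters) drives the
run; every stage writes CSV/JSON under the output directory and the manifest
records the seed, the parameter echo and per-stage status, so a run is fully
reproducible from its manifest.  All randomness flows from one root seed,
split per stage, so stages can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import pdxnet
from pdxnet import cluster as clustermod
from pdxnet import diagnostics, efficacy, enrichment, normalize, simulate
from pdxnet.io import (
    ExpressionMatrix,
    read_gmt,
    read_metadata,
    read_trial,
    write_gmt,
    write_metadata,
    write_trial,
)

STAGES = ["simulate", "normalize", "classify", "enrich", "cluster", "respond"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    seed: int
    outdir: str
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    inputs: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)
    enrich: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    respond: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if "seed" not in raw:
            raise ValueError("config must set a seed (required for stochastic stages)")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        stages = {s: True for s in STAGES}
        stages.update(cfg.stages or {})
        cfg.stages = stages
        return cfg

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed split from the root seed."""
        child = np.random.SeedSequence(self.seed, spawn_key=(STAGES.index(stage),))
        return int(child.generate_state(1)[0] % (2**31))


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=str) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the manifest dict.

    Any stage failure aborts the run with :class:`StageError`; the manifest
    written so far marks the run incomplete.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "pdxnet",
        "version": pdxnet.__version__,
        "seed": config.seed,
        "config": {
            "stages": config.stages,
            "inputs": config.inputs,
            "simulate": config.simulate,
            "classify": config.classify,
            "enrich": config.enrich,
            "cluster": config.cluster,
            "respond": config.respond,
        },
        "stage_status": {},
        "complete": False,
    }

    state: dict = {}
    for stage in STAGES:
        if not config.stages.get(stage, True):
            manifest["stage_status"][stage] = "skipped"
            continue
        try:
            _STAGE_FUNCS[stage](config, outdir, state)
            manifest["stage_status"][stage] = "ok"
        except Exception as exc:  # noqa: BLE001 - repackaged with stage name
            manifest["stage_status"][stage] = f"failed: {exc}"
            _dump_json(manifest, outdir / "manifest.json")
            raise StageError(stage, exc) from exc

    manifest["complete"] = True
    _dump_json(manifest, outdir / "manifest.json")
    return manifest


def _stage_simulate(config: PipelineConfig, outdir: Path, state: dict) -> None:
    seed = config.stage_seed("simulate")
    cohort_cfg = simulate.CohortConfig(**{"seed": seed, **config.simulate.get("cohort", {})})
    trial_cfg = simulate.TrialConfig(**{"seed": seed + 1, **config.simulate.get("trial", {})})
    expr, meta = simulate.generate_expression_cohort(cohort_cfg)
    trial = simulate.generate_pdx_trial(trial_cfg)
    expr.to_tsv(outdir / "expression_counts.tsv")
    write_metadata(meta, outdir / "metadata.tsv")
    write_trial(trial, outdir / "trial.csv")
    write_gmt(
        {"tumorigenic_network": list(cohort_cfg.target_set)},
        outdir / "gene_sets.gmt",
        description="paracrine signaling set",
    )
    state.update(counts=expr, metadata=meta, trial=trial,
                 gene_sets={"tumorigenic_network": list(cohort_cfg.target_set)})


def _load_counts(config: PipelineConfig, state: dict) -> ExpressionMatrix:
    if "counts" not in state:
        state["counts"] = ExpressionMatrix.from_tsv(config.inputs["expression"])
    return state["counts"]


def _load_metadata(config: PipelineConfig, state: dict) -> pd.DataFrame:
    if "metadata" not in state:
        state["metadata"] = read_metadata(config.inputs["metadata"])
    return state["metadata"]


def _stage_normalize(config: PipelineConfig, outdir: Path, state: dict) -> None:
    counts = _load_counts(config, state)
    transformed, sf = normalize.normalize(counts)
    transformed.to_tsv(outdir / "expression_log2.tsv")
    sf.to_csv(outdir / "size_factors.csv", header=True)
    state["log2"] = transformed


def _stage_classify(config: PipelineConfig, outdir: Path, state: dict) -> None:
    params = {
        "gene": simulate.MARKER_GENE,
        "cutoff": diagnostics.DEFAULT_CUTOFF,
        "truth_column": "histology",
        "truth_positive": "A",
        **config.classify,
    }
    expr = state["log2"]
    meta = _load_metadata(config, state).loc[expr.sample_ids]
    values = expr.data.loc[params["gene"]]
    pred = diagnostics.classify_by_cutoff(values, params["cutoff"])
    truth = (meta[params["truth_column"]] == params["truth_positive"]).to_numpy()
    result = diagnostics.evaluate_marker(pred, truth)
    report = {"params": params, **result.to_dict()}
    _dump_json(report, outdir / "marker_diagnostics.json")
    state["diagnostics"] = result


def _stage_enrich(config: PipelineConfig, outdir: Path, state: dict) -> None:
    params = {
        "set_name": "tumorigenic_network",
        "iterations": 2000,
        "mode": "smoothed",
        "tau": 1.0,
        "score_mode": "max_diff",
        "exclude_set": False,
        **config.enrich,
    }
    if "gene_sets" not in state:
        state["gene_sets"] = read_gmt(config.inputs["gene_sets"])
    members = state["gene_sets"][params["set_name"]]
    gene_set = enrichment.GeneSet(params["set_name"], members)
    results = enrichment.permutation_test(
        state["log2"],
        gene_set,
        iterations=params["iterations"],
        mode=params["mode"],
        seed=config.stage_seed("enrich"),
        tau=params["tau"],
        score_mode=params["score_mode"],
        exclude_set=params["exclude_set"],
    )
    frame = enrichment.permutation_frame(results)
    frame.to_csv(outdir / "enrichment.csv")
    state["enrichment"] = frame


def _stage_cluster(config: PipelineConfig, outdir: Path, state: dict) -> None:
    k = int(config.cluster.get("k", 2))
    expr = state["log2"]
    tree = clustermod.hierarchical_cluster(expr)
    labels = clustermod.cut_tree(tree, k=k)
    tree.merge_table().to_csv(outdir / "cluster_merges.csv", index=False)
    labels.to_csv(outdir / "cluster_labels.csv", header=True)
    meta = _load_metadata(config, state).loc[expr.sample_ids]
    if "resistant" in meta.columns:
        summary = clustermod.resistance_by_cluster(labels, meta["resistant"])
        summary.to_csv(outdir / "cluster_resistance.csv")
        state["cluster_resistance"] = summary
    state["cluster_labels"] = labels


def _stage_respond(config: PipelineConfig, outdir: Path, state: dict) -> None:
    params = {
        "window": None,
        "cr_threshold": efficacy.CR_THRESHOLD,
        "pr_threshold": efficacy.PR_THRESHOLD,
        "pd_threshold": efficacy.PD_THRESHOLD,
        "metric": "volume",
        "loss_threshold": 0.05,
        **config.respond,
    }
    if "trial" not in state:
        state["trial"] = read_trial(config.inputs["trial"])
    trial = state["trial"]
    window = params["window"]
    if isinstance(window, str):
        lo, hi = window.split(":")
        window = (float(lo), float(hi))
    calls = efficacy.response_calls(
        trial,
        window=window,
        cr_threshold=params["cr_threshold"],
        pr_threshold=params["pr_threshold"],
        pd_threshold=params["pd_threshold"],
        metric=params["metric"],
    )
    tol = efficacy.tolerability(trial, loss_threshold=params["loss_threshold"])
    calls_out = calls.join(tol[["max_weight_loss_pct", "tolerability_flag"]])
    calls_out.to_csv(outdir / "response_calls.csv")
    summary = efficacy.cohort_summary(calls)
    _dump_json(summary.reset_index().to_dict(orient="records"), outdir / "cohort_summary.json")
    state["response_calls"] = calls
    state["cohort_summary"] = summary


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "normalize": _stage_normalize,
    "classify": _stage_classify,
    "enrich": _stage_enrich,
    "cluster": _stage_cluster,
    "respond": _stage_respond,
}
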