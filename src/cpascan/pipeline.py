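"""Reproducible multi-stage runs with config, manifests and checksums.

``run_pipeline`` executes an ordered subset of the stages

    simulate -> build-data -> featurize -> train -> evaluate

against a single :class:`RunConfig`.  Each stage records its parameters and
the SHA-256 of every file it writes in ``manifest.json`` under the run
directory; rerunning with an identical config and seed reproduces identical
checksums for the deterministic stages.  Later stages consume in-memory
artifacts of earlier ones and fail with a pointer to the missing stage when
run out of order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from cpascan import datasets, evaluation, models, simulate
from cpascan.datasets import (
    DEFAULT_NEGATIVE_RATIO,
    make_positive_windows,
    select_constitutive,
    split_by_chromosome,
    subsample_negatives,
    tile_negatives,
)
from cpascan.features import BASELINE_GRID, FeatureMatrix, assemble_matrix, feature_names
from cpascan.models import ModelConfig, TrainedModel, train
from cpascan.motifs import default_baseline_registry
from cpascan.simulate import GeneratorSpec, TruthSet, generate

STAGES = ("simulate", "build-data", "featurize", "train", "evaluate")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Global configuration of one pipeline run.

    ``generator`` fields override :class:`GeneratorSpec` defaults; every
    dataset constant (window 500, step 100, flank 250, 30:1 subsampling,
    30-fold evaluation excess, learner strengths) is an explicit key.
    """

    outdir: str = "cpascan_run"
    seed: int = 0
    generator: dict = field(default_factory=dict)
    window_length: int = 500
    step: int = 100
    flank: int = 250
    max_overlap_frac: float = 0.10
    negative_ratio: int = DEFAULT_NEGATIVE_RATIO
    negative_excess: float = 30.0
    learner: str = "linear"
    n_trees: int = 300  # desk-scale default; full-scale runs use 30 000
    lr_C: float = models.BASELINE_LR_C

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _require(artifacts: dict, key: str, stage: str, needed_by: str):
    if key not in artifacts:
        raise PipelineError(
            f"stage '{needed_by}' needs outputs of stage '{stage}'; run it first"
        )
    return artifacts[key]


def run_pipeline(
    config: RunConfig,
    stages: Sequence[str] = STAGES,
    artifacts: dict | None = None,
) -> dict:
    """Execute the requested stages in order; returns the run manifest.

    ``artifacts`` (optional) carries in-memory products between partial
    invocations within one process.
    """
    for s in stages:
        if s not in STAGES:
            raise PipelineError(f"unknown stage {s!r}; choose from {STAGES}")
    stages = [s for s in STAGES if s in stages]
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = artifacts if artifacts is not None else {}
    manifest_path = outdir / "manifest.json"
    manifest: dict = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    registry = default_baseline_registry()

    for stage in stages:
        entry: dict = {"params": {}, "outputs": {}}
        if stage == "simulate":
            spec = GeneratorSpec(seed=config.seed, **config.generator)
            truth = generate(spec)
            paths = truth.write(outdir / "data")
            artifacts["truth"] = truth
            entry["params"] = simulate._spec_to_jsonable(spec)
            entry["outputs"] = {str(p): _sha256(p) for p in paths.values()}
        elif stage == "build-data":
            truth: TruthSet = _require(artifacts, "truth", "simulate", stage)
            chosen, dropped = select_constitutive(
                truth.all_known_sites, truth.gene_models()
            )
            positives = make_positive_windows(
                chosen, truth.sequences, flank=config.flank
            )
            negatives = tile_negatives(
                truth.gene_models(),
                truth.sequences,
                truth.all_known_sites,
                window=config.window_length,
                step=config.step,
                max_overlap_frac=config.max_overlap_frac,
                flank=config.flank,
            )
            pos_train, pos_test, _ = split_by_chromosome(positives)
            neg_train, neg_test, _ = split_by_chromosome(negatives)
            neg_train = subsample_negatives(
                neg_train, len(pos_train), ratio=config.negative_ratio,
                seed=config.seed,
            )
            artifacts["train_windows"] = pos_train + neg_train
            artifacts["test_windows"] = pos_test + neg_test
            artifacts["constitutive"] = chosen
            counts_path = outdir / "dataset_counts.json"
            counts = {
                "n_constitutive": len(chosen),
                "n_dropped_genes": len(dropped),
                "n_train_pos": len(pos_train),
                "n_train_neg": len(neg_train),
                "n_test_pos": len(pos_test),
                "n_test_neg": len(neg_test),
            }
            counts_path.write_text(json.dumps(counts, indent=2) + "\n")
            entry["params"] = {
                "window_length": config.window_length,
                "step": config.step,
                "flank": config.flank,
                "max_overlap_frac": config.max_overlap_frac,
                "negative_ratio": config.negative_ratio,
            }
            entry["outputs"] = {str(counts_path): _sha256(counts_path)}
        elif stage == "featurize":
            train_w = _require(artifacts, "train_windows", "build-data", stage)
            test_w = _require(artifacts, "test_windows", "build-data", stage)
            artifacts["train_matrix"] = assemble_matrix(train_w, registry, BASELINE_GRID)
            artifacts["test_matrix"] = assemble_matrix(test_w, registry, BASELINE_GRID)
            for name in ("train_matrix", "test_matrix"):
                m: FeatureMatrix = artifacts[name]
                path = outdir / f"{name}.npz"
                np.savez_compressed(
                    path, values=m.values, labels=m.labels,
                    feature_names=np.array(m.feature_names_),
                )
                entry["outputs"][str(path)] = _sha256(path)
            entry["params"] = {"n_features": artifacts["train_matrix"].n_features}
        elif stage == "train":
            matrix = _require(artifacts, "train_matrix", "featurize", stage)
            if config.learner == "forest":
                mc = ModelConfig.forest(n_trees=config.n_trees, seed=config.seed)
            else:
                mc = ModelConfig.linear(C=config.lr_C, seed=config.seed)
            model = train(mc, matrix)
            artifacts["model"] = model
            path = outdir / "model.joblib"
            model.save(path)
            entry["params"] = dataclasses.asdict(mc)
            entry["outputs"] = {str(path): _sha256(path)}
        elif stage == "evaluate":
            model = _require(artifacts, "model", "train", stage)
            matrix = _require(artifacts, "test_matrix", "featurize", stage)
            result = evaluation.evaluate(
                model, matrix, negative_excess=config.negative_excess,
                seed=config.seed,
            )
            path = outdir / "evaluation.json"
            result.to_json(path)
            artifacts["eval_result"] = result
            entry["params"] = {"negative_excess": config.negative_excess}
            entry["outputs"] = {str(path): _sha256(path)}
            entry["auroc"] = result.auroc
            entry["auprc"] = result.auprc
        manifest[stage] = entry

    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
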