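"""End-to-end orchestration: feature building, training, prediction,
top-up driver calling and evaluation.

The top-up rule assigns each patient a driver list of (by default) five
genes: the patient's damaged canonical drivers come first, and ranked
predictions are appended until the target is reached or the patient's
damaged genes are exhausted — reflecting the assumption that a developed
cancer carries at least five driver events.  Cohorts with fewer than 200
samples are analysed in the pan-cancer setting, larger ones
cancer-specifically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io, metrics, model as model_mod
from .annotation import GeneAnnotation
from .errors import InputError
from .features import build_molecular_features, join_features
from .model import TrainedModel, reduced_grid, build_parameter_grid

logger = logging.getLogger(__name__)

DEFAULT_TARGET_DRIVERS = 5
DEFAULT_COHORT_SIZE_THRESHOLD = 200


@dataclass
class DriverCall:
    """One patient's final driver list.

    Damaged canonical drivers always precede topped-up predictions; the
    ``provenance`` entry for each gene is ``canonical_damaged`` or
    ``syssvm_topup``.
    """

    sample_id: str
    genes: list[str]
    provenance: list[str]
    target: int = DEFAULT_TARGET_DRIVERS

    @property
    def n_canonical(self) -> int:
        return sum(p == "canonical_damaged" for p in self.provenance)

    @property
    def n_topup(self) -> int:
        return sum(p == "syssvm_topup" for p in self.provenance)


def top_up(
    sample_id: str,
    canonical_damaged: list[str],
    ranked_predictions: list[str],
    target: int = DEFAULT_TARGET_DRIVERS,
) -> DriverCall:
    """Top up a patient's damaged canonical drivers with ranked predictions.

    If the patient already has `target` or more damaged canonical drivers,
    they are all returned and nothing is added.  Otherwise predictions are
    appended in rank order until the list reaches `target` or the
    predictions run out (short lists are allowed).  `ranked_predictions`
    must not contain the patient's canonical damaged genes.
    """
    canonical = sorted(dict.fromkeys(canonical_damaged))
    overlap = set(canonical) & set(ranked_predictions)
    if overlap:
        raise InputError(f"ranked predictions contain canonical damaged genes: {sorted(overlap)}")
    genes = list(canonical)
    provenance = ["canonical_damaged"] * len(genes)
    for gene in ranked_predictions:
        if len(genes) >= target:
            break
        genes.append(gene)
        provenance.append("syssvm_topup")
    return DriverCall(sample_id=sample_id, genes=genes, provenance=provenance, target=target)


def choose_setting(cohort_size: int, threshold: int = DEFAULT_COHORT_SIZE_THRESHOLD) -> str:
    """Pan-cancer for small cohorts (size strictly below `threshold`),
    cancer-specific otherwise."""
    if cohort_size < 0:
        raise InputError("cohort size cannot be negative")
    return "pan_cancer" if cohort_size < threshold else "cancer_specific"


def call_drivers(
    features: pd.DataFrame,
    predictions: pd.DataFrame,
    annotation: GeneAnnotation,
    target: int = DEFAULT_TARGET_DRIVERS,
) -> list[DriverCall]:
    """Apply the top-up rule to every sample in the cohort.

    A sample's canonical damaged genes are its damaged canonical drivers as
    present in the feature table (mode of action not re-filtered: a damaged
    canonical driver counts as a driver by default).
    """
    canonical_by_sample: dict[str, list[str]] = {}
    for row in features.itertuples(index=False):
        if annotation.category(row.gene) == "canonical":
            canonical_by_sample.setdefault(row.sample, []).append(row.gene)
    calls = []
    pred_sorted = predictions.sort_values(["sample", "rank"])
    pred_by_sample = {s: list(g["gene"]) for s, g in pred_sorted.groupby("sample")}
    for sample in sorted(features["sample"].unique()):
        canon = sorted(set(canonical_by_sample.get(sample, [])))
        ranked = [g for g in pred_by_sample.get(sample, []) if g not in set(canon)]
        calls.append(top_up(sample, canon, ranked, target=target))
    return calls


def driver_calls_frame(calls: list[DriverCall]) -> pd.DataFrame:
    rows = []
    for call in calls:
        for pos, (gene, prov) in enumerate(zip(call.genes, call.provenance), start=1):
            rows.append({"sample": call.sample_id, "position": pos, "gene": gene, "provenance": prov})
    return pd.DataFrame(rows, columns=["sample", "position", "gene", "provenance"])


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    mutations: str
    properties: str
    annotation: str
    cnvs: str | None = None
    ploidy: str | None = None
    output_dir: str = "driversvm_out"
    mode: str = "auto"
    cohort_size_threshold: int = DEFAULT_COHORT_SIZE_THRESHOLD
    target_drivers: int = DEFAULT_TARGET_DRIVERS
    seed: int = 0
    grid: str = "default"
    max_iterations: int = 2000
    window: int = 100
    model_path: str | None = None

    def __post_init__(self) -> None:
        if self.cohort_size_threshold <= 0:
            raise InputError("cohort_size_threshold must be positive")
        if self.mode not in ("auto", "pan_cancer", "cancer_specific"):
            raise InputError(f"unknown mode {self.mode!r}")
        if self.grid not in ("default", "reduced"):
            raise InputError(f"unknown grid spec {self.grid!r} (use 'default' or 'reduced')")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise InputError(f"config file {path} is not a mapping")
        known = set(cls.__dataclass_fields__)
        bad = set(raw) - known
        if bad:
            raise InputError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write the output bundle.

    Stages: read and validate inputs, build per-(sample, gene) features,
    train (or load) the multi-kernel model, score and rank the prediction
    set, top up patient driver lists, evaluate, and write a manifest that
    suffices to re-run the analysis bit-identically.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage annotate: reading inputs")
    mutations = io.read_mutations(config.mutations)
    cnvs = io.read_cnvs(config.cnvs) if config.cnvs else None
    ploidy = io.read_ploidy(config.ploidy) if config.ploidy else None
    properties = io.read_properties(config.properties)
    annotation = io.read_annotation(config.annotation)

    molecular = build_molecular_features(mutations, cnvs, ploidy)
    features, join_report = join_features(molecular, properties)
    n_samples = features["sample"].nunique()
    setting = config.mode if config.mode != "auto" else choose_setting(n_samples, config.cohort_size_threshold)
    logger.info("stage features: %d damaged entries, %d samples, setting=%s", len(features), n_samples, setting)

    if config.model_path:
        logger.info("stage train: loading model from %s", config.model_path)
        model = TrainedModel.load(config.model_path)
    else:
        grid = build_parameter_grid() if config.grid == "default" else reduced_grid()
        model = model_mod.train(
            features,
            annotation,
            grid=grid,
            max_iterations=config.max_iterations,
            window=config.window,
            seed=config.seed,
        )
        model.save(out / "model.joblib")

    logger.info("stage predict: scoring prediction set")
    predictions = model_mod.score_predictions(model, features)
    io.write_tsv(predictions, out / "predictions.tsv")

    logger.info("stage topup: calling drivers")
    calls = call_drivers(features, predictions, annotation, target=config.target_drivers)
    io.write_tsv(driver_calls_frame(calls), out / "driver_calls.tsv")

    logger.info("stage evaluate")
    report = metrics.evaluate_predictions(predictions, annotation, k=config.target_drivers)
    io.write_tsv(report, out / "evaluation_per_sample.tsv")
    io.write_tsv(metrics.cohort_summary(report.drop(columns="sample")), out / "evaluation_summary.tsv")

    inputs = {"mutations": config.mutations, "properties": config.properties, "annotation": config.annotation}
    if config.cnvs:
        inputs["cnvs"] = config.cnvs
    if config.ploidy:
        inputs["ploidy"] = config.ploidy
    manifest = {
        "package_version": __version__,
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
        "setting": setting,
        "input_checksums": {k: _checksum(v) for k, v in inputs.items()},
        "n_samples": int(n_samples),
        "n_feature_entries": int(len(features)),
        "n_training_entries": len(model.training_roster),
        "n_dropped_genes": len(join_report.dropped_genes),
        "kernel_sensitivities": model.sensitivities,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "output_dir": str(out),
        "setting": setting,
        "model": model,
        "predictions": predictions,
        "driver_calls": calls,
        "evaluation": report,
        "manifest": manifest,
    }
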