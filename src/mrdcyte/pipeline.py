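"""End-to-end orchestration: simulate -> gate -> score -> stats -> models.

A single structured YAML config drives every stage; the run manifest
(seed, resolved config, config hash, package versions) is sufficient
to regenerate every number bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gating import GateTree, default_gate_tree, gate_events
from .laip import build_reference_ranges, quantify_mrd_from_gating
from .models import RFConfig, fit_logistic, forward_select, train_rf_eval
from .panel import B_STAGES, STUDY_MARKERS
from .simulate import (
    CohortConfig,
    SampleConfig,
    simulate_cohort,
    simulate_reference_samples,
    simulate_sample,
)
from .stats import roc_auc

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised with the full list of configuration problems."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


@dataclass
class SimulateSection:
    n_reference: int = 5
    reference_events: int = 100_000
    n_patients: int = 6
    patient_events: int = 200_000
    blast_fractions: tuple[float, ...] = (0.0, 1e-3, 5e-3)
    cohort_samples: int = 201
    mrd_prevalence: float = 0.398

    def __post_init__(self) -> None:
        self.blast_fractions = tuple(self.blast_fractions)


@dataclass
class GatingSection:
    derive_from_reference: bool = True
    thresholds: dict = field(default_factory=dict)


@dataclass
class ScoringSection:
    min_blast_events: int = 10
    min_laips: int = 2


@dataclass
class ModelsSection:
    ntree: int = 100
    mtry: int = 4
    train_fraction: float = 0.7
    p_enter: float = 0.05
    p_remove: float = 0.10


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "mrdcyte_run"
    verbosity: str = "info"
    simulate: SimulateSection = field(default_factory=SimulateSection)
    gating: GatingSection = field(default_factory=GatingSection)
    scoring: ScoringSection = field(default_factory=ScoringSection)
    models: ModelsSection = field(default_factory=ModelsSection)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "simulate": SimulateSection, "gating": GatingSection,
    "scoring": ScoringSection, "models": ModelsSection,
}


def _build_config(data: dict) -> PipelineConfig:
    errors: list[str] = []
    top_fields = {"seed", "out_dir", "verbosity", *_SECTIONS}
    for key in set(data) - top_fields:
        errors.append(f"unknown top-level key: {key!r}")
    kwargs = {k: data[k] for k in ("seed", "out_dir", "verbosity") if k in data}
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            errors.append(f"section {name!r} must be a mapping")
            continue
        known = set(cls.__dataclass_fields__)
        for key in set(section) - known:
            errors.append(f"unknown key {name}.{key}")
        try:
            kwargs[name] = cls(**{k: v for k, v in section.items() if k in known})
        except (TypeError, ValueError) as exc:
            errors.append(f"invalid section {name!r}: {exc}")
    cfg = PipelineConfig(**kwargs)
    sim = cfg.simulate
    if not 0.0 <= sim.mrd_prevalence <= 1.0:
        errors.append("simulate.mrd_prevalence must lie in [0, 1]")
    if any(not 0.0 <= f <= 1.0 for f in sim.blast_fractions):
        errors.append("simulate.blast_fractions entries must lie in [0, 1]")
    if sim.n_reference < 1:
        errors.append("simulate.n_reference must be >= 1")
    if errors:
        raise ConfigError(errors)
    return cfg


def validate_config(path) -> PipelineConfig:
    """Load + schema-check a YAML config; empty file yields full defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(["config root must be a mapping"])
    return _build_config(data)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(config.to_dict())), fh,
                       sort_keys=False)


@dataclass
class ReportBundle:
    """Paths and tables produced by one pipeline run."""

    out_dir: Path
    mrd_report: pd.DataFrame
    roc_table: pd.DataFrame
    full_model: pd.DataFrame
    forward_steps: pd.DataFrame
    importance: pd.DataFrame
    manifest: dict


def _stage_timer(name: str):
    logger.info("stage %s started", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all stages in order, persisting intermediates and reports."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    sim = config.simulate

    t0 = _stage_timer("simulate-reference")
    references = simulate_reference_samples(
        sim.n_reference, sim.reference_events, seed=seed)
    logger.info("simulated %d reference samples (%.1fs)", len(references),
                time.perf_counter() - t0)

    t0 = _stage_timer("gate-tree")
    if config.gating.derive_from_reference:
        tree = default_gate_tree(references, thresholds=config.gating.thresholds)
    else:
        tree = default_gate_tree(thresholds=config.gating.thresholds)
    tree.save(out / "gate_tree.yaml")

    reference_results = [gate_events(s, tree) for s in references]
    ranges = build_reference_ranges(reference_results)
    ranges.to_tsv(out / "reference_ranges.tsv")

    t0 = _stage_timer("score-patients")
    rows = []
    stage_mfis: dict[str, dict[str, list[float]]] = {
        s: {m: [] for m in STUDY_MARKERS} for s in B_STAGES}
    blast_mfis: dict[str, list[float]] = {m: [] for m in STUDY_MARKERS}
    for result in reference_results:
        for stage in B_STAGES:
            if result.counts.get(stage, 0) > 0:
                for m in STUDY_MARKERS:
                    stage_mfis[stage][m].append(result.population_mfi(m, stage))
    for i in range(sim.n_patients):
        frac = sim.blast_fractions[i % len(sim.blast_fractions)]
        sample = simulate_sample(SampleConfig(
            total_events=sim.patient_events, blast_fraction=frac,
            seed=seed * 7919 + 1000 + i, sample_id=f"patient_{i:02d}"))
        result = gate_events(sample, tree)
        mrd = quantify_mrd_from_gating(
            result, sample, ranges,
            min_events=config.scoring.min_blast_events,
            min_laips=config.scoring.min_laips)
        rows.append({
            "sample_id": mrd.sample_id, "true_blast_fraction": frac,
            "blast_events": mrd.blast_event_count,
            "raw_percent": mrd.raw_percent,
            "correction_factor": mrd.correction_factor,
            "corrected_percent": mrd.corrected_percent,
            "n_laips": mrd.n_laips, "mrd_positive": mrd.positive,
        })
        if mrd.positive:
            for m in STUDY_MARKERS:
                blast_mfis[m].append(result.population_mfi(m, "residual_blast"))
    mrd_report = pd.DataFrame(rows)
    mrd_report.to_csv(out / "sample_mrd_report.tsv", sep="\t", index=False)
    logger.info("scored %d patient samples (%.1fs)", sim.n_patients,
                time.perf_counter() - t0)

    roc_rows = {}
    for m in STUDY_MARKERS:
        row = {}
        for stage in B_STAGES:
            if blast_mfis[m] and stage_mfis[stage][m]:
                row[stage] = roc_auc(blast_mfis[m], stage_mfis[stage][m]).auc
            else:
                row[stage] = float("nan")
        roc_rows[m] = row
    roc_table = pd.DataFrame.from_dict(roc_rows, orient="index")
    roc_table.to_csv(out / "roc_table.tsv", sep="\t")

    t0 = _stage_timer("cohort-models")
    cohort = simulate_cohort(CohortConfig(
        n_samples=sim.cohort_samples, mrd_prevalence=sim.mrd_prevalence,
        seed=seed + 17))
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
    features = cohort.drop(columns=["MRD"])
    full = fit_logistic(features, cohort["MRD"])
    full_table = full.coefficients.copy()
    full_table.to_csv(out / "logit_full.tsv", sep="\t")
    path = forward_select(features, cohort["MRD"],
                          p_enter=config.models.p_enter,
                          p_remove=config.models.p_remove)
    forward_steps = pd.DataFrame([
        {"step": s.step, "entered": s.entered,
         "minus2LL": s.fit.minus2ll, "nagelkerke_r2": s.fit.nagelkerke,
         "hl_p": s.hl.p if s.hl else float("nan"),
         "accuracy": s.fit.accuracy, "sensitivity": s.fit.sensitivity,
         "specificity": s.fit.specificity}
        for s in path.steps])
    forward_steps.to_csv(out / "logit_forward.tsv", sep="\t", index=False)
    importance, evaluation = train_rf_eval(cohort, RFConfig(
        ntree=config.models.ntree, mtry=config.models.mtry,
        train_fraction=config.models.train_fraction, seed=seed + 29))
    importance.to_csv(out / "rf_importance.tsv", sep="\t")
    with open(out / "rf_eval.json", "w") as fh:
        json.dump({**asdict(evaluation), "ci": list(evaluation.ci)}, fh,
                  indent=2)
    logger.info("cohort models done (%.1fs)", time.perf_counter() - t0)

    resolved = config.to_dict()
    manifest = {
        "seed": seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": resolved,
        "config_sha256": hashlib.sha256(
            json.dumps(resolved, sort_keys=True).encode()).hexdigest(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return ReportBundle(out, mrd_report, roc_table, full_table,
                        forward_steps, importance, manifest)
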