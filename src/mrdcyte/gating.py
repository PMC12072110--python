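"""Hierarchical gating of BM events into B-lineage stages and blasts.

The tree mirrors the clinical strategy: nucleated events (SYTO41+) are
selected first, B-lineage events (CD19+ and/or CD22+) next, then the
four normal maturation stages are claimed by explicit phenotype
conjunctions (first match wins, in maturation order):

* pre-B-I   — CD34+ / CD10 high / CD19 low / CD20 low-neg / CD45 low
* pre-B-II  — CD34- / CD10 low / CD19 high / CD20 low / CD45 dim
* immature  — CD34- / CD10+ / CD20++ / CD19+
* mature    — CD34- / CD10- / CD19+ / CD20+

B-lineage events claimed by no stage are candidate blasts; they are
kept only when CD20 is not mature-bright and at least one aberrancy
channel (CD73, CD304 by default) exceeds its threshold — an explicit,
per-event leukemia-associated-immunophenotype condition.  Everything
else nucleated is labeled ``other`` (this includes T cells) and
SYTO41-negative events are ``debris``.  Every event receives exactly
one terminal label.

Manual gate positions are never published for this assay, so every
boundary is an explicit, serializable :class:`GateRule`, either
configured or derived from non-leukemic reference samples
(:func:`default_gate_tree`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.mixture import GaussianMixture

from .panel import B_STAGES, STUDY_MARKERS
from .simulate import EventMatrix

logger = logging.getLogger(__name__)

GATE_LABELS: tuple[str, ...] = (
    "debris", "other", "pre_b_1", "pre_b_2", "immature_b", "mature_b",
    "residual_blast",
)


class EmptyPopulationError(LookupError):
    """Raised when an MFI is requested for a population with no events."""


@dataclass(frozen=True)
class GateRule:
    """One boundary: ``channel <op> threshold`` with op in {">", "<="}."""

    channel: str
    op: str
    threshold: float

    def __post_init__(self) -> None:
        if self.op not in (">", "<="):
            raise ValueError("op must be '>' or '<='")

    def mask(self, values: pd.DataFrame) -> np.ndarray:
        col = values[self.channel].to_numpy()
        return col > self.threshold if self.op == ">" else col <= self.threshold

    def to_dict(self) -> dict:
        return {"channel": self.channel, "op": self.op,
                "threshold": float(self.threshold)}


@dataclass(frozen=True)
class StageGate:
    """Conjunction of rules defining one maturation stage."""

    label: str
    rules: tuple[GateRule, ...]

    def mask(self, values: pd.DataFrame) -> np.ndarray:
        out = np.ones(len(values), dtype=bool)
        for rule in self.rules:
            out &= rule.mask(values)
        return out


@dataclass(frozen=True)
class GateTree:
    """Full hierarchy: nucleated -> lineage -> stages -> blast."""

    nucleated: GateRule
    lineage: tuple[GateRule, ...]          # any-of
    stages: tuple[StageGate, ...]          # ordered, first match wins
    blast_guard: tuple[GateRule, ...]      # all-of (e.g. CD20 not bright)
    aberrancy: tuple[GateRule, ...]        # any-of, per-event LAIP condition

    @property
    def required_channels(self) -> set[str]:
        chans = {self.nucleated.channel}
        chans.update(r.channel for r in self.lineage)
        for stage in self.stages:
            chans.update(r.channel for r in stage.rules)
        chans.update(r.channel for r in self.blast_guard)
        chans.update(r.channel for r in self.aberrancy)
        return chans

    def to_dict(self) -> dict:
        return {
            "nucleated": self.nucleated.to_dict(),
            "lineage": [r.to_dict() for r in self.lineage],
            "stages": [{"label": s.label, "rules": [r.to_dict() for r in s.rules]}
                       for s in self.stages],
            "blast_guard": [r.to_dict() for r in self.blast_guard],
            "aberrancy": [r.to_dict() for r in self.aberrancy],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GateTree":
        rule = lambda d: GateRule(d["channel"], d["op"], d["threshold"])
        return cls(
            nucleated=rule(data["nucleated"]),
            lineage=tuple(rule(d) for d in data["lineage"]),
            stages=tuple(StageGate(s["label"],
                                   tuple(rule(d) for d in s["rules"]))
                         for s in data["stages"]),
            blast_guard=tuple(rule(d) for d in data["blast_guard"]),
            aberrancy=tuple(rule(d) for d in data["aberrancy"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "GateTree":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: Configured default gate positions (fluorescence units on the
#: simulator's linear scale); every one can be overridden or re-derived
#: from reference samples.
DEFAULT_THRESHOLDS: dict[str, float] = {
    "syto41_pos": 500.0,
    "cd19_pos": 400.0,
    "cd22_pos": 1000.0,
    "cd34_pos": 1000.0,
    "cd10_neg_max": 500.0,
    "cd10_high_min": 2500.0,
    "cd19_low_max": 1500.0,
    "cd20_low_max": 1000.0,
    "cd20_high_min": 2000.0,
    "cd45_low_max": 1400.0,
    "cd45_dim_min": 1200.0,
    "cd45_dim_max": 2400.0,
    "cd73_aberrant": 2500.0,
    "cd304_aberrant": 900.0,
}


def build_gate_tree(thresholds: dict[str, float] | None = None) -> GateTree:
    """Assemble the stage hierarchy from a named-threshold table."""
    t = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        unknown = set(thresholds) - set(t)
        if unknown:
            raise ValueError(f"unknown threshold names: {sorted(unknown)}")
        t.update(thresholds)
    stages = (
        StageGate("pre_b_1", (
            GateRule("CD34", ">", t["cd34_pos"]),
            GateRule("CD10", ">", t["cd10_high_min"]),
            GateRule("CD19", "<=", t["cd19_low_max"]),
            GateRule("CD20", "<=", t["cd20_low_max"]),
            GateRule("CD45", "<=", t["cd45_low_max"]),
        )),
        StageGate("pre_b_2", (
            GateRule("CD34", "<=", t["cd34_pos"]),
            GateRule("CD10", ">", t["cd10_neg_max"]),
            GateRule("CD10", "<=", t["cd10_high_min"]),
            GateRule("CD19", ">", t["cd19_low_max"]),
            GateRule("CD20", "<=", t["cd20_high_min"]),
            GateRule("CD45", ">", t["cd45_dim_min"]),
            GateRule("CD45", "<=", t["cd45_dim_max"]),
        )),
        StageGate("immature_b", (
            GateRule("CD34", "<=", t["cd34_pos"]),
            GateRule("CD10", ">", t["cd10_neg_max"]),
            GateRule("CD10", "<=", t["cd10_high_min"]),
            GateRule("CD20", ">", t["cd20_high_min"]),
            GateRule("CD19", ">", t["cd19_pos"]),
        )),
        StageGate("mature_b", (
            GateRule("CD34", "<=", t["cd34_pos"]),
            GateRule("CD10", "<=", t["cd10_neg_max"]),
            GateRule("CD20", ">", t["cd20_high_min"]),
            GateRule("CD19", ">", t["cd19_pos"]),
        )),
    )
    return GateTree(
        nucleated=GateRule("Syto41", ">", t["syto41_pos"]),
        lineage=(GateRule("CD19", ">", t["cd19_pos"]),
                 GateRule("CD22", ">", t["cd22_pos"])),
        stages=stages,
        blast_guard=(GateRule("CD20", "<=", t["cd20_high_min"]),),
        aberrancy=(GateRule("CD73", ">", t["cd73_aberrant"]),
                   GateRule("CD304", ">", t["cd304_aberrant"])),
    )


# ---------------------------------------------------------------------------
# Data-driven thresholds
# ---------------------------------------------------------------------------

def estimate_split_threshold(values, default: float | None = None,
                             min_separation: float = 2.0,
                             random_state: int = 0) -> float:
    """Valley between the negative and positive modes of one channel.

    Fits a two-component Gaussian mixture and returns the density
    minimum between the component means.  When the modes are closer
    than ``min_separation`` pooled SDs the channel is treated as
    unimodal and the configured ``default`` is returned (logged).
    """
    x = np.asarray(values, dtype=float).ravel()
    if len(x) > 100_000:
        x = np.random.default_rng(random_state).choice(x, 100_000, replace=False)
    gm = GaussianMixture(2, random_state=random_state, n_init=1).fit(x[:, None])
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    lo, hi = np.argsort(means)
    if means[hi] - means[lo] < min_separation * max(sds):
        if default is None:
            raise ValueError("channel is unimodal and no default threshold given")
        logger.warning("unimodal channel; falling back to default threshold %g",
                       default)
        return float(default)
    grid = np.linspace(means[lo], means[hi], 512)
    dens = np.exp(gm.score_samples(grid[:, None]))
    return float(grid[np.argmin(dens)])


def default_gate_tree(reference_samples: list[EventMatrix] | None = None,
                      thresholds: dict[str, float] | None = None,
                      aberrancy_quantile: float = 0.9995) -> GateTree:
    """Gate tree with thresholds derived from non-leukemic reference samples.

    Single-boundary channels (SYTO41, CD19, CD34) are split at the
    valley between their modes; the LAIP aberrancy boundaries are set
    at an extreme quantile of reference CD20-low B-progenitor events.
    Channels whose reference distribution is unimodal keep the
    configured defaults.  Without reference samples the configured
    defaults are used as-is.
    """
    t = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        t.update(thresholds)
    if reference_samples:
        pooled = pd.concat([s.values for s in reference_samples],
                           ignore_index=True)
        for key, channel in (("syto41_pos", "Syto41"), ("cd19_pos", "CD19"),
                             ("cd34_pos", "CD34")):
            t[key] = estimate_split_threshold(pooled[channel], default=t[key])
        nucleated = pooled["Syto41"].to_numpy() > t["syto41_pos"]
        b_lineage = nucleated & (pooled["CD19"].to_numpy() > t["cd19_pos"])
        progenitor = b_lineage & (pooled["CD20"].to_numpy() <= t["cd20_high_min"])
        if progenitor.sum() >= 100:
            for key, channel in (("cd73_aberrant", "CD73"),
                                 ("cd304_aberrant", "CD304")):
                t[key] = float(np.quantile(pooled.loc[progenitor, channel],
                                           aberrancy_quantile))
    return build_gate_tree(t)


# ---------------------------------------------------------------------------
# Event labeling
# ---------------------------------------------------------------------------

@dataclass
class GatingResult:
    """Per-event labels plus per-population counts and MFI vectors."""

    labels: np.ndarray
    counts: dict[str, int]
    mfi: pd.DataFrame  # index = populations with >= 1 event, columns = channels
    sample_id: str = "sample"

    @property
    def n_events(self) -> int:
        return int(sum(self.counts.values()))

    def count(self, population: str) -> int:
        return int(self.counts.get(population, 0))

    def population_mfi(self, marker: str, population: str) -> float:
        if self.counts.get(population, 0) == 0:
            raise EmptyPopulationError(
                f"population {population!r} has no events in {self.sample_id!r}")
        return float(self.mfi.loc[population, marker])

    def summary(self) -> pd.DataFrame:
        out = self.mfi.copy()
        out.insert(0, "n_events", [self.counts[p] for p in out.index])
        return out


def gate_events(events: EventMatrix, tree: GateTree) -> GatingResult:
    """Assign every event exactly one terminal label and summarize."""
    values = events.values
    if len(values) == 0:
        empty = pd.DataFrame(columns=values.columns)
        return GatingResult(np.empty(0, dtype=object), {}, empty,
                            events.sample_id)
    missing = sorted(tree.required_channels - set(values.columns))
    if missing:
        raise ValueError(f"event table is missing required channels: {missing}")

    labels = np.full(len(values), "other", dtype=object)
    nucleated = tree.nucleated.mask(values)
    labels[~nucleated] = "debris"

    lineage = np.zeros(len(values), dtype=bool)
    for rule in tree.lineage:
        lineage |= rule.mask(values)
    lineage &= nucleated

    unclaimed = lineage.copy()
    for stage in tree.stages:
        hit = unclaimed & stage.mask(values)
        labels[hit] = stage.label
        unclaimed &= ~hit

    guard = unclaimed.copy()
    for rule in tree.blast_guard:
        guard &= rule.mask(values)
    aberrant = np.zeros(len(values), dtype=bool)
    for rule in tree.aberrancy:
        aberrant |= rule.mask(values)
    labels[guard & aberrant] = "residual_blast"

    series = pd.Series(labels, index=values.index, name="population")
    counts = series.value_counts().to_dict()
    mfi = values.groupby(series, observed=True).mean()
    return GatingResult(labels, {k: int(v) for k, v in counts.items()},
                        mfi, events.sample_id)


def population_mfi(result: GatingResult, marker: str, population: str) -> float:
    """Arithmetic mean of one channel over one gated population."""
    return result.population_mfi(marker, population)
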