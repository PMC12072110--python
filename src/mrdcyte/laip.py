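"""LAIP grading against hematogone reference ranges and MRD quantification.

The scoring core of the assay:

* **Reference ranges** — per marker, the lowest and highest population
  MFI observed across the normal B-cell progenitor stages (pre-B-I,
  pre-B-II, immature B) of a non-leukemic reference cohort.
* **Ordinal expression grade** — 0 below the envelope (no expression),
  3 above it (bright/over-expression), 1/2 inside it split at the
  envelope midpoint (dim vs moderate).  Grades 1-3 are "positive".
  A marker is a LAIP when its grade is 0 or 3 (outside the envelope).
* **MRD call** — a sample is MRD-positive when the blast gate holds at
  least 10 events and the blast population carries at least two LAIPs.
* **Corrected MRD%** — the raw blast percentage (of all acquired
  events) multiplied by a debris correction factor CF, the ratio of
  the CD19+ fraction among nucleated (SYTO41+) events to the CD19+
  fraction among all events; CF restores the nucleated-cell
  denominator that unlysed debris inflates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import round_half_up
from .gating import DEFAULT_THRESHOLDS, GateTree, GatingResult, gate_events
from .panel import COEXPRESSION_MARKERS, PROGENITOR_STAGES, STUDY_MARKERS
from .simulate import EventMatrix

#: MRD positivity rule: a cluster of >= 10 blast events with >= 2 LAIPs.
MIN_BLAST_EVENTS = 10
MIN_LAIPS = 2


@dataclass(frozen=True)
class ReferenceRange:
    """Per-marker [min, max] MFI envelope of normal B-cell progenitors."""

    table: pd.DataFrame  # index = marker, columns = min_ref, max_ref
    n_reference_samples: int

    def __post_init__(self) -> None:
        if (self.table["min_ref"] > self.table["max_ref"]).any():
            raise ValueError("min_ref must not exceed max_ref")

    @property
    def markers(self) -> list[str]:
        return list(self.table.index)

    def bounds(self, marker: str) -> tuple[float, float]:
        if marker not in self.table.index:
            raise KeyError(f"no reference range defined for marker {marker!r}")
        row = self.table.loc[marker]
        return float(row["min_ref"]), float(row["max_ref"])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "marker", out.index)
        out["n_reference_samples"] = self.n_reference_samples
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ReferenceRange":
        table = pd.read_csv(path, sep="\t").set_index("marker")
        n = int(table.pop("n_reference_samples").iloc[0])
        return cls(table[["min_ref", "max_ref"]], n)


def build_reference_ranges(normal_results: Iterable[GatingResult],
                           populations: tuple[str, ...] = PROGENITOR_STAGES,
                           markers: tuple[str, ...] = STUDY_MARKERS,
                           ) -> ReferenceRange:
    """Min/max envelope of per-sample progenitor-population MFIs.

    Each reference sample contributes one MFI per marker per gated
    progenitor population; the envelope is the elementwise min/max over
    all those values.  Raises if no sample has any progenitor events.
    """
    rows = []
    n_samples = 0
    for result in normal_results:
        n_samples += 1
        for pop in populations:
            if result.counts.get(pop, 0) > 0:
                rows.append(result.mfi.loc[pop, list(markers)])
    if not rows:
        raise ValueError("no B-cell progenitor events in any reference sample")
    stacked = pd.DataFrame(rows)
    table = pd.DataFrame({"min_ref": stacked.min(), "max_ref": stacked.max()})
    return ReferenceRange(table.loc[list(markers)], n_samples)


@dataclass(frozen=True)
class ExpressionGrade:
    """Ordinal 0-3 expression grade; grades >= 1 count as positive."""

    grade: int
    positive: bool

    @property
    def is_laip(self) -> bool:
        return self.grade in (0, 3)


def grade_expression(mfi: float, ranges: ReferenceRange, marker: str,
                     midpoint: float | None = None) -> ExpressionGrade:
    """Grade one population MFI against the reference envelope.

    0 below ``min_ref``; 3 above ``max_ref``; 1 up to the envelope
    midpoint, 2 above it.  The 1/2 boundary defaults to the arithmetic
    midpoint and is configurable.
    """
    lo, hi = ranges.bounds(marker)
    if midpoint is None:
        midpoint = (lo + hi) / 2.0
    if mfi < lo:
        grade = 0
    elif mfi > hi:
        grade = 3
    elif mfi <= midpoint:
        grade = 1
    else:
        grade = 2
    return ExpressionGrade(grade, grade >= 1)


@dataclass(frozen=True)
class LAIPProfile:
    """Per-sample marker grades and the count of aberrant markers."""

    grades: Mapping[str, ExpressionGrade]
    sample_id: str = "sample"

    @property
    def n_laips(self) -> int:
        return sum(g.is_laip for g in self.grades.values())

    def positive_markers(self) -> frozenset:
        return frozenset(m for m, g in self.grades.items() if g.positive)


def profile_from_mfis(mfis: Mapping[str, float], ranges: ReferenceRange,
                      sample_id: str = "sample") -> LAIPProfile:
    grades = {m: grade_expression(v, ranges, m) for m, v in mfis.items()}
    return LAIPProfile(grades, sample_id)


class HematogoneReference(BaseEstimator, TransformerMixin):
    """Reference-range grader with the scikit-learn estimator protocol.

    ``fit`` consumes a table of per-sample progenitor-population MFIs
    (rows = one gated progenitor population of one reference sample,
    columns = markers) and stores the min/max envelope; ``transform``
    maps a table of population MFIs to ordinal 0-3 grades.
    """

    def __init__(self, markers: tuple[str, ...] = STUDY_MARKERS):
        self.markers = markers

    def fit(self, X: pd.DataFrame, y=None) -> "HematogoneReference":
        X = pd.DataFrame(X)
        missing = [m for m in self.markers if m not in X.columns]
        if missing:
            raise ValueError(f"fit table is missing markers: {missing}")
        if len(X) == 0:
            raise ValueError("fit table must contain at least one row")
        sub = X[list(self.markers)]
        table = pd.DataFrame({"min_ref": sub.min(), "max_ref": sub.max()})
        self.ranges_ = ReferenceRange(table, n_reference_samples=len(X))
        self.n_features_in_ = len(self.markers)
        return self

    @classmethod
    def from_gating_results(cls, results: Iterable[GatingResult],
                            markers: tuple[str, ...] = STUDY_MARKERS,
                            ) -> "HematogoneReference":
        est = cls(markers=markers)
        est.ranges_ = build_reference_ranges(results, markers=markers)
        est.n_features_in_ = len(markers)
        return est

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "ranges_"):
            raise ValueError("HematogoneReference is not fitted")
        X = pd.DataFrame(X)
        out = pd.DataFrame(index=X.index, columns=list(self.markers), dtype=int)
        for m in self.markers:
            out[m] = [grade_expression(v, self.ranges_, m).grade for v in X[m]]
        return out


# ---------------------------------------------------------------------------
# Co-expression of the three most frequently positive aberrancy markers
# ---------------------------------------------------------------------------

_CATEGORY_BY_COUNT = {0: "negative", 1: "single", 2: "double", 3: "triple"}
COEXPRESSION_CATEGORIES = ("triple", "double", "single", "negative")


@dataclass(frozen=True)
class CoexpressionCategory:
    category: str
    markers: frozenset = field(default_factory=frozenset)


def coexpression_category(grades: Mapping[str, ExpressionGrade],
                          markers: tuple[str, ...] = COEXPRESSION_MARKERS,
                          ) -> CoexpressionCategory:
    """Triple/double/single/negative positivity over CD99, CD58, CD44."""
    missing = [m for m in markers if m not in grades]
    if missing:
        raise ValueError(f"grades missing for markers: {missing}")
    positive = frozenset(m for m in markers if grades[m].positive)
    return CoexpressionCategory(_CATEGORY_BY_COUNT[len(positive)], positive)


def tally_coexpression(profiles: Iterable[LAIPProfile]) -> pd.DataFrame:
    """Counts and one-decimal percentages per co-expression category."""
    cats = [coexpression_category(p.grades).category for p in profiles]
    if not cats:
        raise ValueError("at least one profile is required")
    counts = pd.Series(cats).value_counts()
    counts = counts.reindex(COEXPRESSION_CATEGORIES, fill_value=0)
    total = int(counts.sum())
    pct = counts.map(lambda c: round_half_up(100.0 * c / total, 1))
    return pd.DataFrame({"count": counts, "percent": pct})


# ---------------------------------------------------------------------------
# MRD quantification
# ---------------------------------------------------------------------------

def mrd_call(blast_event_count: int, profile: LAIPProfile,
             min_events: int = MIN_BLAST_EVENTS,
             min_laips: int = MIN_LAIPS) -> bool:
    """MRD positivity: >= ``min_events`` blast events with >= ``min_laips`` LAIPs."""
    if blast_event_count < 0:
        raise ValueError("blast_event_count must be >= 0")
    return blast_event_count >= min_events and profile.n_laips >= min_laips


def correction_factor(pct_cd19_of_syto41_in_syto_tube: float,
                      pct_cd19_of_all_events_in_mrd_tube: float) -> float:
    """Debris correction factor CF.

    Ratio of the CD19+ B-cell percentage among nucleated (SYTO41+)
    events to the CD19+ percentage among all acquired events.
    """
    if pct_cd19_of_all_events_in_mrd_tube <= 0:
        raise ValueError("CD19+ percentage of all events must be > 0")
    if pct_cd19_of_syto41_in_syto_tube <= 0:
        raise ValueError("CD19+ percentage of nucleated events must be > 0")
    return pct_cd19_of_syto41_in_syto_tube / pct_cd19_of_all_events_in_mrd_tube


def corrected_mrd(raw_percent: float, cf: float) -> float:
    """Corrected MRD% = raw% x CF (no internal rounding)."""
    if raw_percent < 0:
        raise ValueError("raw_percent must be >= 0")
    if cf <= 0:
        raise ValueError("correction factor must be > 0")
    return raw_percent * cf


def correction_factor_from_events(events: EventMatrix,
                                  syto_threshold: float | None = None,
                                  cd19_threshold: float | None = None) -> float:
    """CF computed from one event matrix (stand-in for the two-tube assay)."""
    if syto_threshold is None:
        syto_threshold = DEFAULT_THRESHOLDS["syto41_pos"]
    if cd19_threshold is None:
        cd19_threshold = DEFAULT_THRESHOLDS["cd19_pos"]
    syto = events.values["Syto41"].to_numpy() > syto_threshold
    cd19 = events.values["CD19"].to_numpy() > cd19_threshold
    if not syto.any():
        raise ValueError("no nucleated (SYTO41+) events")
    pct_nucleated = 100.0 * (cd19 & syto).sum() / syto.sum()
    pct_all = 100.0 * cd19.sum() / len(cd19)
    return correction_factor(pct_nucleated, pct_all)


@dataclass(frozen=True)
class MRDResult:
    """Raw and debris-corrected MRD percentages with the positivity call."""

    raw_percent: float
    correction_factor: float
    corrected_percent: float
    positive: bool
    blast_event_count: int
    n_laips: int
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        expected = self.raw_percent * self.correction_factor
        if not np.isclose(self.corrected_percent, expected, rtol=0, atol=1e-12):
            raise ValueError("corrected_percent must equal raw_percent x CF")


def quantify_mrd(events: EventMatrix, tree: GateTree,
                 reference: ReferenceRange,
                 min_events: int = MIN_BLAST_EVENTS,
                 min_laips: int = MIN_LAIPS) -> MRDResult:
    """Gate one sample, grade its blast population, and quantify MRD."""
    result = gate_events(events, tree)
    return quantify_mrd_from_gating(result, events, reference,
                                    min_events=min_events, min_laips=min_laips)


def quantify_mrd_from_gating(result: GatingResult, events: EventMatrix,
                             reference: ReferenceRange,
                             min_events: int = MIN_BLAST_EVENTS,
                             min_laips: int = MIN_LAIPS) -> MRDResult:
    n_blast = result.counts.get("residual_blast", 0)
    raw = 100.0 * n_blast / result.n_events
    cf = correction_factor_from_events(events)
    if n_blast > 0:
        mfis = {m: result.population_mfi(m, "residual_blast")
                for m in reference.markers}
        profile = profile_from_mfis(mfis, reference, result.sample_id)
        n_laips = profile.n_laips
        positive = mrd_call(n_blast, profile, min_events, min_laips)
    else:
        n_laips = 0
        positive = False
    return MRDResult(raw, cf, raw * cf, positive, n_blast, n_laips,
                     result.sample_id)
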