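"""Marker panel definitions for the 14-color BCP-ALL MRD assay.

The assay combines eight markers under study (aberrancy/maturation
markers scored against the hematogone reference) with a backbone of
lineage/maturation channels used for gating, the SYTO41 DNA/RNA stain
used to select nucleated events, and the two scatter channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The eight markers graded against the hematogone reference ranges.
STUDY_MARKERS: tuple[str, ...] = (
    "CD44", "CD304", "CD99", "CD86", "CD73", "CD123", "CD22", "CD58",
)

#: Backbone gating channels (B-lineage, maturation, viability, scatter).
BACKBONE_CHANNELS: tuple[str, ...] = (
    "CD45", "CD19", "CD20", "CD10", "CD34", "CD38", "Syto41", "SSC", "FSC",
)

#: The three most frequently positive aberrancy markers, tallied jointly.
COEXPRESSION_MARKERS: tuple[str, ...] = ("CD99", "CD58", "CD44")

#: Population labels produced by the simulator and the gating tree.
POPULATIONS: tuple[str, ...] = (
    "residual_blast", "pre_b_1", "pre_b_2", "immature_b", "mature_b",
    "t_cell", "debris",
)

#: Normal B-cell progenitor (hematogone + immature) stages used to build
#: reference ranges.
PROGENITOR_STAGES: tuple[str, ...] = ("pre_b_1", "pre_b_2", "immature_b")

#: All B-lineage maturation stages gated by the tree.
B_STAGES: tuple[str, ...] = ("pre_b_1", "pre_b_2", "immature_b", "mature_b")


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered channel list for one stained sample.

    Invariants: channel names unique and the eight study markers present.
    """

    markers: tuple[str, ...] = field(
        default=STUDY_MARKERS + BACKBONE_CHANNELS
    )

    def __post_init__(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("panel channel names must be unique")
        missing = [m for m in STUDY_MARKERS if m not in self.markers]
        if missing:
            raise ValueError(f"panel is missing study markers: {missing}")

    def __iter__(self):
        return iter(self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    def __contains__(self, channel: str) -> bool:
        return channel in self.markers


def default_panel() -> MarkerPanel:
    """The full 17-channel panel (8 study markers + 9 backbone channels)."""
    return MarkerPanel()
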