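"""Antibody panel definition for the multiplexed ion-count assay.

The default panel mirrors a myeloma-focused metal-labeled antibody panel:
34 unique antibody targets (two BCMA clones share one metal tag and are
collapsed onto a single channel) plus two iridium DNA intercalators, for 36
image channels in total. Each marker carries a role tag:

``clinical``
    surface markers used clinically to immunophenotype plasma cells.
``target``
    candidate therapeutic-target markers compared between precursor and
    overt-disease plasma cells.
``lineage``
    lineage / microenvironment markers used for cell typing and gating.
``intercalator``
    DNA intercalator channels; positive over every nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["PanelDefinition", "default_panel", "CLINICAL_MARKERS", "TARGET_MARKERS"]

#: Clinical plasma-cell immunophenotyping markers (used for embeddings).
CLINICAL_MARKERS = ("CD45", "CD56", "CD27", "CD81", "CD117", "CD28")

#: The 14 candidate therapeutic-target markers compared across conditions.
TARGET_MARKERS = (
    "BCMA",
    "ICAM3",
    "CD221",
    "CS1",
    "CD74",
    "MUM1",
    "CD229",
    "CD44",
    "IGLL5",
    "CyclinD1",
    "UBA52",
    "CD317",
    "Blimp1",
    "pS6",
)

_DEFAULT_ROLES: dict[str, str] = {
    # lineage / microenvironment
    "CD20": "lineage",
    "CD38": "lineage",
    "CD4": "lineage",
    "lambda": "lineage",
    "CD31": "lineage",
    "kappa": "lineage",
    "CD138": "lineage",
    "CD63": "lineage",
    "BAFF": "lineage",
    "CD3": "lineage",
    "CD61": "lineage",
    "CD45RO": "lineage",
    "CD8a": "lineage",
    "HLA-DR": "lineage",
    # clinical immunophenotyping
    "CD81": "clinical",
    "CD28": "clinical",
    "CD117": "clinical",
    "CD27": "clinical",
    "CD56": "clinical",
    "CD45": "clinical",
    # candidate targets
    "MUM1": "target",
    "BCMA": "target",
    "CS1": "target",
    "Blimp1": "target",
    "ICAM3": "target",
    "CD74": "target",
    "CD221": "target",
    "CD317": "target",
    "CyclinD1": "target",
    "UBA52": "target",
    "pS6": "target",
    "CD44": "target",
    "IGLL5": "target",
    "CD229": "target",
    # DNA intercalators
    "DNA1": "intercalator",
    "DNA2": "intercalator",
}

_VALID_ROLES = frozenset({"clinical", "target", "lineage", "intercalator"})


@dataclass(frozen=True)
class PanelDefinition:
    """Ordered list of marker channels with per-marker role tags.

    Parameters
    ----------
    markers
        Ordered channel names; must be unique.
    roles
        Mapping from marker name to one of ``clinical``, ``target``,
        ``lineage``, ``intercalator``. Every marker must be tagged.
    """

    markers: tuple[str, ...]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            dupes = sorted({m for m in self.markers if list(self.markers).count(m) > 1})
            raise ValueError(f"duplicate marker names in panel: {dupes}")
        missing = [m for m in self.markers if m not in self.roles]
        if missing:
            raise ValueError(f"markers without a role tag: {missing}")
        bad = {m: r for m, r in self.roles.items() if r not in _VALID_ROLES}
        if bad:
            raise ValueError(f"invalid role tags: {bad}")

    def __len__(self) -> int:
        return len(self.markers)

    def index(self, marker: str) -> int:
        """Channel index of *marker*; raises ``KeyError`` for unknown names."""
        try:
            return self.markers.index(marker)
        except ValueError:
            raise KeyError(f"marker {marker!r} not in panel") from None

    @property
    def intercalators(self) -> tuple[str, ...]:
        return tuple(m for m in self.markers if self.roles[m] == "intercalator")

    @property
    def antibodies(self) -> tuple[str, ...]:
        return tuple(m for m in self.markers if self.roles[m] != "intercalator")

    def by_role(self, role: str) -> tuple[str, ...]:
        if role not in _VALID_ROLES:
            raise ValueError(f"unknown role {role!r}")
        return tuple(m for m in self.markers if self.roles[m] == role)


def default_panel() -> PanelDefinition:
    """The default 36-channel panel: 34 antibody targets + 2 DNA intercalators.

    The assay uses 35 metal-labeled antibodies, but the two BCMA clones share
    one metal tag (Nd150) and therefore land on a single image channel.
    """
    markers = tuple(_DEFAULT_ROLES)
    panel = PanelDefinition(markers=markers, roles=dict(_DEFAULT_ROLES))
    assert len(panel) == 36
    assert len(panel.intercalators) == 2
    return panel
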