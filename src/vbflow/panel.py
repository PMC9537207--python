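"""Panel configuration for multi-tube TCR Vbeta cytometry.

A commercial Vbeta typing kit spreads 24 Vbeta-family antibodies over 8
staining tubes, 3 antibodies per tube, on top of a shared "backbone" of
lineage/differentiation/exhaustion markers measured in every tube.  The
:class:`PanelDesign` records which family is read out in which tube; every
downstream frequency uses it to find the tube-aware denominator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import yaml

__all__ = [
    "DEFAULT_VB_FAMILIES",
    "DEFAULT_BACKBONE",
    "SCATTER_CHANNELS",
    "VB_NEGATIVE",
    "TubeSpec",
    "PanelDesign",
    "PanelConfigError",
    "generate_panel_design",
    "vb_channel",
]

#: The 24 families of an 8-tube/3-antibody Vbeta kit.
DEFAULT_VB_FAMILIES: tuple[str, ...] = (
    "Vb1", "Vb2", "Vb3", "Vb4", "Vb5.1", "Vb5.2", "Vb5.3", "Vb7.1",
    "Vb7.2", "Vb8", "Vb9", "Vb11", "Vb12", "Vb13.1", "Vb13.2", "Vb13.6",
    "Vb14", "Vb16", "Vb17", "Vb18", "Vb20", "Vb21.3", "Vb22", "Vb23",
)

#: Surface markers stained in every tube.
DEFAULT_BACKBONE: tuple[str, ...] = (
    "CD3", "CD4", "CD8", "CCR7", "CD45RA", "CD27", "CD28", "TIGIT", "PD-1",
)

SCATTER_CHANNELS: tuple[str, ...] = ("FSC-A", "SSC-A")

#: Gate label for events negative for all three of a tube's Vbeta antibodies.
VB_NEGATIVE = "Vb-"


class PanelConfigError(ValueError):
    """Raised for an inconsistent panel configuration."""


def vb_channel(family: str) -> str:
    """Fluorescence channel name carrying a Vbeta family's antibody."""
    return f"TCR_{family}"


@dataclass(frozen=True)
class TubeSpec:
    """One staining tube: its id and the Vbeta families it detects."""

    tube_id: str
    vb_families: tuple[str, ...]

    @property
    def vb_channels(self) -> tuple[str, ...]:
        return tuple(vb_channel(f) for f in self.vb_families)


@dataclass(frozen=True)
class PanelDesign:
    """Mapping of Vbeta families to tubes plus the shared marker backbone.

    Invariants (checked on construction): family labels are unique across
    tubes, and every tube shares the same backbone.
    """

    tubes: tuple[TubeSpec, ...]
    backbone_markers: tuple[str, ...] = DEFAULT_BACKBONE
    scatter_channels: tuple[str, ...] = SCATTER_CHANNELS
    _family_to_tube: dict[str, str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for tube in self.tubes:
            for fam in tube.vb_families:
                if fam in seen:
                    raise PanelConfigError(
                        f"Vbeta family {fam!r} assigned to both tube "
                        f"{seen[fam]!r} and tube {tube.tube_id!r}"
                    )
                seen[fam] = tube.tube_id
        object.__setattr__(self, "_family_to_tube", seen)

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(f for tube in self.tubes for f in tube.vb_families)

    @property
    def n_tubes(self) -> int:
        return len(self.tubes)

    def tube_of(self, family: str) -> str:
        """Tube id whose antibody set contains ``family``."""
        try:
            return self._family_to_tube[family]
        except KeyError:
            raise KeyError(f"Vbeta family {family!r} not in panel") from None

    def tube(self, tube_id: str) -> TubeSpec:
        for t in self.tubes:
            if t.tube_id == tube_id:
                return t
        raise KeyError(f"tube {tube_id!r} not in panel")

    def event_channels(self, tube_id: str) -> tuple[str, ...]:
        """All channels recorded for a tube, in canonical order."""
        return (
            self.scatter_channels
            + self.backbone_markers
            + self.tube(tube_id).vb_channels
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "backbone_markers": list(self.backbone_markers),
            "scatter_channels": list(self.scatter_channels),
            "tubes": [
                {"tube_id": t.tube_id, "vb_families": list(t.vb_families)}
                for t in self.tubes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PanelDesign":
        return cls(
            tubes=tuple(
                TubeSpec(t["tube_id"], tuple(t["vb_families"])) for t in d["tubes"]
            ),
            backbone_markers=tuple(d.get("backbone_markers", DEFAULT_BACKBONE)),
            scatter_channels=tuple(d.get("scatter_channels", SCATTER_CHANNELS)),
        )

    def to_file(self, path) -> None:
        path = str(path)
        with open(path, "w", encoding="utf-8") as fh:
            if path.endswith((".yaml", ".yml")):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
            else:
                json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_file(cls, path) -> "PanelDesign":
        with open(str(path), encoding="utf-8") as fh:
            text = fh.read()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        return cls.from_dict(data)


def generate_panel_design(
    n_tubes: int = 8,
    families_per_tube: int = 3,
    families: tuple[str, ...] | None = None,
    backbone_markers: tuple[str, ...] = DEFAULT_BACKBONE,
) -> PanelDesign:
    """Partition ``families`` into ``n_tubes`` tubes of ``families_per_tube``.

    Defaults reproduce the 8-tube / 3-antibody layout covering 24 families.
    Raises :class:`PanelConfigError` if the family count is not exactly
    ``n_tubes * families_per_tube``.
    """
    if families is None:
        families = DEFAULT_VB_FAMILIES
    if n_tubes < 1 or families_per_tube < 1:
        raise PanelConfigError("n_tubes and families_per_tube must be >= 1")
    if n_tubes * families_per_tube != len(families):
        raise PanelConfigError(
            f"{len(families)} Vbeta families cannot be split into "
            f"{n_tubes} tubes of {families_per_tube}"
        )
    tubes = tuple(
        TubeSpec(
            tube_id=f"tube{i + 1}",
            vb_families=tuple(
                families[i * families_per_tube : (i + 1) * families_per_tube]
            ),
        )
        for i in range(n_tubes)
    )
    return PanelDesign(tubes=tubes, backbone_markers=backbone_markers)
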