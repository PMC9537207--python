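"""Event-file reading/writing and per-tube Vbeta gating.

Events live in a per-tube CSV (one row per event, one column per channel,
comma separator, ``.`` decimal, UTF-8) plus optional ``tube_id`` and
``vb_gate`` columns.  Gating assigns every event either one of the tube's
three Vbeta-family labels or the shared negative label ``Vb-``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .panel import VB_NEGATIVE, PanelDesign, vb_channel

__all__ = [
    "ChannelError",
    "EmptyInputError",
    "DEFAULT_CHANNEL_ALIASES",
    "TubeEventMatrix",
    "GateSpec",
    "read_events",
    "write_events",
    "apply_gates",
]


class ChannelError(ValueError):
    """A required channel is missing or misconfigured."""


class EmptyInputError(ValueError):
    """An event file contained no events."""


#: Instrument $PnS strings vary; extend this table for local conventions.
DEFAULT_CHANNEL_ALIASES: dict[str, str] = {
    "CD197": "CCR7",
    "CD279": "PD-1",
    "PD1": "PD-1",
    "FSC-H": "FSC-A",  # only used when FSC-A itself is absent
}

META_COLUMNS = ("tube_id", "sample_id", "vb_gate", "population", "true_vb")


@dataclass
class TubeEventMatrix:
    """Events x channels for one staining tube of one sample.

    ``data`` holds numeric intensities in panel channel order;
    ``gate_labels`` (aligned to ``data``) holds each event's Vbeta gate,
    one of the tube's three family labels or :data:`~vbflow.panel.VB_NEGATIVE`.
    """

    tube_id: str
    sample_id: str
    data: pd.DataFrame
    gate_labels: pd.Series | None = None
    timepoint: str | None = None
    truth: pd.DataFrame | None = None  # optional per-event ground truth

    def __post_init__(self) -> None:
        if self.gate_labels is not None and len(self.gate_labels) != len(self.data):
            raise ValueError("gate_labels length does not match event count")

    @property
    def n_events(self) -> int:
        return len(self.data)

    def validate_gates(self, panel: PanelDesign) -> None:
        """Check gate labels reference only this tube's families."""
        if self.gate_labels is None:
            return
        allowed = set(panel.tube(self.tube_id).vb_families) | {VB_NEGATIVE}
        bad = set(self.gate_labels.unique()) - allowed
        if bad:
            raise ChannelError(
                f"gate labels {sorted(bad)} are not families of tube "
                f"{self.tube_id!r}"
            )


def _normalize_columns(
    columns: list[str], aliases: dict[str, str]
) -> dict[str, str]:
    """Map lowercase, alias-resolved names to the original file columns."""
    alias_lc = {k.lower(): v for k, v in aliases.items()}
    out: dict[str, str] = {}
    for col in columns:
        canon = alias_lc.get(col.strip().lower(), col.strip())
        out.setdefault(canon.lower(), col)
    return out


def read_events(
    path,
    panel: PanelDesign,
    tube_id: str,
    sample_id: str = "",
    fmt: str = "csv",
    aliases: dict[str, str] | None = None,
) -> TubeEventMatrix:
    """Read one tube's events, normalizing channel names and order.

    Channel matching is case-insensitive after applying the alias table.
    A ``vb_gate`` column, if present, is carried as externally supplied
    gate labels.
    """
    if fmt != "csv":
        raise ValueError(f"unsupported event format {fmt!r} (csv only)")
    if aliases is None:
        aliases = DEFAULT_CHANNEL_ALIASES
    raw = pd.read_csv(path)
    if raw.empty:
        raise EmptyInputError(f"{path}: no events")
    lookup = _normalize_columns(list(raw.columns), aliases)
    wanted = panel.event_channels(tube_id)
    missing = [ch for ch in wanted if ch.lower() not in lookup]
    if missing:
        raise ChannelError(
            f"{path}: missing channel(s) {', '.join(missing)}"
        )
    data = pd.DataFrame(
        {ch: pd.to_numeric(raw[lookup[ch.lower()]]) for ch in wanted}
    )
    gate = None
    if "vb_gate" in lookup:
        gate = raw[lookup["vb_gate"]].astype(str).reset_index(drop=True)
        gate.name = "vb_gate"
    tube = TubeEventMatrix(
        tube_id=tube_id,
        sample_id=sample_id or str(raw[lookup["sample_id"]].iloc[0])
        if "sample_id" in lookup
        else sample_id,
        data=data.reset_index(drop=True),
        gate_labels=gate,
    )
    tube.validate_gates(panel)
    return tube


def write_events(tube: TubeEventMatrix, path) -> None:
    """Write a tube's events as CSV with tube_id and vb_gate columns."""
    out = tube.data.copy()
    out.insert(0, "sample_id", tube.sample_id)
    out.insert(1, "tube_id", tube.tube_id)
    if tube.gate_labels is not None:
        out["vb_gate"] = tube.gate_labels.to_numpy()
    out.to_csv(path, index=False, float_format="%.9g")


@dataclass
class GateSpec:
    """Vbeta gating rule for one tube.

    Exactly one mode is active: ``thresholds`` maps each of the tube's
    Vbeta channels to a post-transform positivity cutoff, or
    ``external_labels`` supplies per-event labels verbatim (the route for
    gates drawn by hand in acquisition software).
    """

    thresholds: dict[str, float] | None = None
    external_labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.thresholds is None) == (self.external_labels is None):
            raise ValueError(
                "exactly one of thresholds / external_labels must be set"
            )
        if self.thresholds is not None:
            for ch, thr in self.thresholds.items():
                if not np.isfinite(thr):
                    raise ValueError(f"non-finite threshold for {ch!r}")


def apply_gates(
    tube: TubeEventMatrix, gates: GateSpec, panel: PanelDesign
) -> TubeEventMatrix:
    """Label every event with a Vbeta gate.

    Threshold mode: an event is positive for a family when its channel
    exceeds that channel's threshold; events above several thresholds go
    to the highest-intensity channel (the kit's antibodies are mutually
    exclusive in biology, so conflicts are noise), ties broken by the
    tube's antibody order.  Events below all thresholds are ``Vb-``.
    """
    spec = panel.tube(tube.tube_id)
    if gates.external_labels is not None:
        labels = gates.external_labels.astype(str).reset_index(drop=True)
        if len(labels) != tube.n_events:
            raise ValueError("external label length does not match events")
    else:
        chans = list(spec.vb_channels)
        missing = [c for c in chans if c not in tube.data.columns]
        if missing:
            raise ChannelError(f"tube {tube.tube_id!r} lacks channels {missing}")
        thr = np.array(
            [gates.thresholds.get(c, np.inf) for c in chans], dtype=float
        )
        vals = tube.data[chans].to_numpy(dtype=float)
        above = vals > thr[None, :]
        # Mask sub-threshold channels, then take the brightest remaining;
        # np.argmax's first-hit rule implements the antibody-order tie-break.
        masked = np.where(above, vals, -np.inf)
        winner = np.argmax(masked, axis=1)
        any_pos = above.any(axis=1)
        fams = np.array(spec.vb_families, dtype=object)
        labels = pd.Series(
            np.where(any_pos, fams[winner], VB_NEGATIVE), name="vb_gate"
        )
    out = replace(tube, gate_labels=labels)
    out.validate_gates(panel)
    return out
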