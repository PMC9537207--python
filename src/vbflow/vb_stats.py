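"""Vbeta frequency reconstruction, diversity, and expansion calls.

The central subtlety of multi-tube Vbeta cytometry is the denominator:
each family's antibody only ever sees the cells of its own tube, so a
family's frequency is its positive events divided by the scope events
*originating from that family's tube* (the tube-relative frequency).
After equal downsampling of eight tubes, even a fully monoclonal cluster
shows at most 1/8 = 12.5% of its events positive for one family — for
each positive cell, seven Vbeta-negative cells from the other tubes sit
in the same cluster.  Both conventions (within-cluster and tube-relative)
are reported.

Diversity uses the inverse Simpson index over tube-relative frequencies
renormalized across detected families; oligoclonal expansions are called
when a cluster's Vbeta profile either fails to join the naive reference's
clade in a hierarchical clustering (correlation distance, average
linkage) or is dominated by a single family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .cluster import ClusterResult, SubsetAssignment
from .panel import PanelDesign
from .preprocess import PooledEventMatrix

__all__ = [
    "VbProfile",
    "DiversityResult",
    "ExpansionCall",
    "event_subset_labels",
    "vb_profile",
    "subset_vb_distribution",
    "cluster_vb_profile",
    "inverse_simpson",
    "call_expansions",
    "expansion_kinetics",
    "kinetics_to_tsv",
]

UNDETECTED = "undetected"


@dataclass
class VbProfile:
    """Per-family Vbeta counts and frequencies for one scope.

    ``table`` is indexed by family with columns:

    - ``tube_id`` — tube carrying the family's antibody
    - ``n_vb_pos`` — scope events gate-positive for the family
    - ``n_tube_scope`` — scope events originating from that tube
    - ``n_scope_total`` — all scope events
    - ``within_cluster_freq`` — n_vb_pos / n_scope_total
    - ``tube_relative_freq`` — n_vb_pos / n_tube_scope (NaN when the tube
      contributed no scope events: missing, not zero)
    - ``vb_pos_share`` — the family's share among all Vbeta+ scope events
    """

    scope: str
    table: pd.DataFrame
    sample_id: str | None = None

    @property
    def n_scope_total(self) -> int:
        return int(self.table["n_scope_total"].iloc[0]) if len(self.table) else 0

    @property
    def n_vb_pos_total(self) -> int:
        return int(self.table["n_vb_pos"].sum())

    @property
    def families(self) -> list[str]:
        return list(self.table.index)

    def tube_relative(self, fill_missing: float | None = None) -> pd.Series:
        s = self.table["tube_relative_freq"]
        return s.fillna(fill_missing) if fill_missing is not None else s

    @property
    def dominant_family(self) -> str:
        """Family with the highest tube-relative frequency, or
        ``"undetected"`` when the scope holds no Vbeta+ event."""
        if self.n_vb_pos_total == 0:
            return UNDETECTED
        return str(self.table["tube_relative_freq"].idxmax())

    @property
    def dominance(self) -> float:
        """Max tube-relative frequency (0 when no Vbeta+ events)."""
        if self.n_vb_pos_total == 0:
            return 0.0
        return float(self.table["tube_relative_freq"].max())


def vb_profile(
    meta: pd.DataFrame, panel: PanelDesign, scope: str, sample_id: str | None = None
) -> VbProfile:
    """Build a profile from scope events' (tube_id, vb_label) metadata."""
    n_total = len(meta)
    tube_counts = meta["tube_id"].value_counts()
    fam_counts = meta["vb_label"].value_counts()
    n_pos_total = int(
        fam_counts.reindex(panel.families).fillna(0).sum()
    )
    rows = []
    for fam in panel.families:
        tube = panel.tube_of(fam)
        n_tube = int(tube_counts.get(tube, 0))
        n_pos = int(fam_counts.get(fam, 0))
        rows.append(
            {
                "family": fam,
                "tube_id": tube,
                "n_vb_pos": n_pos,
                "n_tube_scope": n_tube,
                "n_scope_total": n_total,
                "within_cluster_freq": n_pos / n_total if n_total else np.nan,
                "tube_relative_freq": n_pos / n_tube if n_tube else np.nan,
                "vb_pos_share": n_pos / n_pos_total if n_pos_total else 0.0,
            }
        )
    table = pd.DataFrame(rows).set_index("family")
    return VbProfile(scope=scope, table=table, sample_id=sample_id)


def event_subset_labels(
    clusters: ClusterResult, assignment: SubsetAssignment
) -> np.ndarray:
    """Per-event subset label, inherited from the event's cluster."""
    lut = {k: assignment.labels[k] for k in assignment.labels}
    return np.array([lut[k] for k in clusters.labels], dtype=object)


def _scoped_meta(
    pooled: PooledEventMatrix, mask: np.ndarray, sample_id: str | None
) -> pd.DataFrame:
    meta = pooled.meta.loc[mask]
    if sample_id is not None:
        meta = meta[meta["sample_id"] == sample_id]
    return meta


def subset_vb_distribution(
    pooled: PooledEventMatrix,
    subset_labels: np.ndarray,
    scope: str,
    sample_id: str | None = None,
) -> VbProfile:
    """Vbeta profile of one biological subset.

    ``subset_labels`` is the per-event subset array (see
    :func:`event_subset_labels`).  Each family's frequency is computed
    against the subset events of the family's own tube; families whose
    tube contributed no scope events are reported missing, not zero.
    """
    mask = np.asarray(subset_labels) == scope
    meta = _scoped_meta(pooled, mask, sample_id)
    if meta.empty:
        raise ValueError(f"subset {scope!r} is empty in every tube")
    return vb_profile(meta, pooled.panel, scope=scope, sample_id=sample_id)


def cluster_vb_profile(
    pooled: PooledEventMatrix,
    clusters: ClusterResult,
    cluster_id: int,
    sample_id: str | None = None,
) -> VbProfile:
    """Vbeta profile of one cluster (both frequency conventions)."""
    mask = clusters.labels == cluster_id
    meta = _scoped_meta(pooled, mask, sample_id)
    if meta.empty:
        raise ValueError(f"cluster {cluster_id} is empty")
    return vb_profile(
        meta, pooled.panel, scope=f"cluster{cluster_id}", sample_id=sample_id
    )


@dataclass
class DiversityResult:
    """Inverse Simpson diversity of a Vbeta profile.

    ``D = 1 / sum(p_i^2)`` with p the tube-relative frequencies
    renormalized over detected families; bounded by the number of
    detected families, equal to it only for a uniform distribution.
    """

    scope: str
    inverse_simpson: float
    n_vb_pos_total: int
    n_detected_families: int


def inverse_simpson(profile: VbProfile) -> DiversityResult:
    """Inverse Simpson index over a profile's tube-relative frequencies.

    Families from empty-tube scopes are excluded (not zero-filled) before
    renormalization so missing tubes cannot inflate evenness.  A scope
    with no Vbeta+ events has undefined diversity (NaN).
    """
    freqs = profile.table["tube_relative_freq"].dropna()
    n_detected = int(freqs.notna().sum())
    total = freqs.sum()
    if profile.n_vb_pos_total == 0 or total == 0:
        return DiversityResult(profile.scope, float("nan"),
                               profile.n_vb_pos_total, n_detected)
    p = (freqs / total).to_numpy(dtype=float)
    p = p[p > 0]
    d = 1.0 / float((p**2).sum())
    return DiversityResult(
        scope=profile.scope,
        inverse_simpson=d,
        n_vb_pos_total=profile.n_vb_pos_total,
        n_detected_families=n_detected,
    )


@dataclass
class ExpansionCall:
    """One oligoclonal-expansion call (possibly spanning merged clusters)."""

    clusters: tuple[int, ...]
    dominant_family: str
    dominance: float
    fingerprint: tuple[str, ...] = ()
    oligoclonal: bool = True
    naive_similarity: float = float("nan")
    total_frequency: float = float("nan")
    sample_id: str | None = None
    timepoint: str | None = None

    @property
    def key(self) -> tuple:
        return (self.dominant_family, self.fingerprint)


def call_expansions(
    profiles: dict[int, VbProfile],
    naive_reference: VbProfile,
    delta: float = 0.5,
    tau: float = 0.8,
    assignment: SubsetAssignment | None = None,
    scope_profile: VbProfile | None = None,
    timepoint: str | None = None,
) -> list[ExpansionCall]:
    """Flag clusters whose Vbeta profile departs from the naive reference.

    Cluster profiles are hierarchically clustered together with the naive
    reference (correlation distance on tube-relative frequency vectors,
    average linkage).  A cluster is oligoclonal when it does not join the
    reference's clade at cophenetic similarity >= ``tau`` (similarity =
    1 - cophenetic distance) OR its dominance exceeds ``delta``.  With
    fewer than two cluster profiles only the dominance rule applies.
    Flagged clusters sharing a dominant family and phenotype fingerprint
    are merged into a single call; ``scope_profile`` (the enclosing
    subset's profile) supplies the tube denominators for each call's
    total frequency.
    """
    ids = sorted(profiles)
    vecs = {k: profiles[k].tube_relative(fill_missing=0.0).to_numpy()
            for k in ids}
    ref_vec = naive_reference.tube_relative(fill_missing=0.0).to_numpy()

    similarity: dict[int, float] = {}
    usable = [k for k in ids if np.std(vecs[k]) > 0]
    if len(usable) >= 2 and np.std(ref_vec) > 0:
        mat = np.vstack([vecs[k] for k in usable] + [ref_vec])
        Z = linkage(mat, method="average", metric="correlation")
        coph = squareform(cophenet(Z))
        for i, k in enumerate(usable):
            similarity[k] = 1.0 - float(coph[i, -1])

    flagged: list[ExpansionCall] = []
    for k in ids:
        prof = profiles[k]
        sim = similarity.get(k, float("nan"))
        in_naive_clade = not np.isnan(sim) and sim >= tau
        dominant = prof.dominance > delta
        if not (dominant or (k in similarity and not in_naive_clade)):
            continue
        if prof.n_vb_pos_total == 0:
            continue  # no Vbeta evidence to call an expansion on
        flagged.append(
            ExpansionCall(
                clusters=(k,),
                dominant_family=prof.dominant_family,
                dominance=prof.dominance,
                fingerprint=assignment.fingerprint(k) if assignment else (),
                naive_similarity=sim,
                sample_id=prof.sample_id,
                timepoint=timepoint,
            )
        )

    # merge flagged clusters sharing (dominant family, fingerprint)
    merged: dict[tuple, ExpansionCall] = {}
    for call in flagged:
        if call.key in merged:
            prev = merged[call.key]
            merged[call.key] = ExpansionCall(
                clusters=prev.clusters + call.clusters,
                dominant_family=call.dominant_family,
                dominance=max(prev.dominance, call.dominance),
                fingerprint=call.fingerprint,
                naive_similarity=np.nanmin(
                    [prev.naive_similarity, call.naive_similarity]
                ),
                sample_id=call.sample_id,
                timepoint=timepoint,
            )
        else:
            merged[call.key] = call
    calls = list(merged.values())

    if scope_profile is not None:
        for i, call in enumerate(calls):
            fam = call.dominant_family
            if fam == UNDETECTED:
                continue
            n_pos = sum(
                int(profiles[k].table.loc[fam, "n_vb_pos"])
                for k in call.clusters
            )
            denom = float(scope_profile.table.loc[fam, "n_tube_scope"])
            calls[i] = ExpansionCall(
                **{**call.__dict__, "total_frequency": n_pos / denom
                   if denom else float("nan")}
            )
    return calls


def expansion_kinetics(
    calls_by_timepoint: dict[str, list[ExpansionCall]],
) -> pd.DataFrame:
    """Track expansions across timepoints.

    Calls are matched by (dominant family, phenotype fingerprint); when a
    family-only match would be ambiguous the fingerprint decides.  The
    result has one row per expansion and one ``total_frequency`` column
    per timepoint; missing entries (expansion absent at that timepoint)
    are NaN, conventionally printed as "ND".  A single timepoint simply
    tabulates the call list.
    """
    timepoints = list(calls_by_timepoint)
    keys: list[tuple] = []
    for tp in timepoints:
        for call in calls_by_timepoint[tp]:
            if call.key not in keys:
                keys.append(call.key)
    if not keys:
        warnings.warn("no expansion present at any timepoint", stacklevel=2)
    rows = []
    for fam, fp in keys:
        row: dict = {"dominant_family": fam, "fingerprint": "/".join(fp)}
        for tp in timepoints:
            match = [c for c in calls_by_timepoint[tp] if c.key == (fam, fp)]
            if not match:
                # fingerprint mismatch fallback: unique family at this timepoint
                fam_only = [
                    c for c in calls_by_timepoint[tp] if c.dominant_family == fam
                ]
                match = fam_only if len(fam_only) == 1 else []
            row[tp] = match[0].total_frequency if match else np.nan
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["dominant_family", "fingerprint"] + timepoints
    )


def kinetics_to_tsv(kinetics: pd.DataFrame, path) -> None:
    """Write a kinetics table with absences printed as ND."""
    out = kinetics.copy()
    tp_cols = [c for c in out.columns if c not in ("dominant_family", "fingerprint")]
    for c in tp_cols:
        out[c] = out[c].map(lambda v: "ND" if pd.isna(v) else f"{v:.6g}")
    out.to_csv(path, sep="\t", index=False)
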