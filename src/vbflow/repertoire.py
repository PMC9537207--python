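"""TRB clonotype-table analysis.

Consumes annotated rearrangement tables (AIRR-style TSV: V gene, CDR3
junction, J gene, read count, productive flag) per sorted subset or
tissue, and provides the companion analyses to the cytometry pipeline:
Shannon diversity, artifact read filtering, CDR3 length spectra with
top-clonotype annotation, cross-sample clonotype overlap, and matching
against an antigen-specificity reference database.

Conventions: within-study clonotype identity is (V gene, nucleotide
junction, J gene) — the most stringent key — while database matching
uses the amino-acid junction; gene calls are normalized to gene level by
stripping allele designators ("*01").  Clonotype frequencies are computed
against the full productive library *before* any read filter, matching
how per-clonotype percentages are conventionally reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClonotypeTable",
    "OverlapResult",
    "SchemaError",
    "normalize_gene",
    "load_clonotypes",
    "filter_low_reads",
    "shannon_diversity",
    "cdr3_spectrum",
    "overlap_clonotypes",
    "match_antigen_db",
    "hla_compatible",
]

REQUIRED_COLUMNS = (
    "sample_id", "v_call", "junction", "junction_aa", "j_call",
    "duplicate_count", "productive",
)

KEY_COLUMNS = ("v_gene", "junction", "j_gene")


class SchemaError(ValueError):
    """A table is missing required columns or is malformed."""


def normalize_gene(call: str) -> str:
    """Strip the allele designator: 'TRBV9*01' -> 'TRBV9'."""
    return str(call).split("*", 1)[0].strip()


def _parse_productive(col: pd.Series) -> pd.Series:
    if col.dtype == bool:
        return col
    return col.astype(str).str.strip().str.upper().isin(("T", "TRUE", "1"))


@dataclass
class ClonotypeTable:
    """Productive TRB clonotypes of one or more samples.

    ``data`` holds one row per (sample, clonotype key), aggregated by
    read sum; ``frequency`` is reads over the sample's total productive
    reads at load time (the pre-filter denominator), and survives later
    read filtering unchanged.
    """

    data: pd.DataFrame
    total_reads: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.total_reads:
            self.total_reads = (
                self.data.groupby("sample_id")["duplicate_count"]
                .sum().astype(int).to_dict()
            )

    @property
    def samples(self) -> list[str]:
        # total_reads keeps sample identity even when a filter empties a
        # sample's rows (an empty repertoire is still a sample)
        return sorted(
            set(self.data["sample_id"].unique()) | set(self.total_reads)
        )

    def sample(self, sample_id: str) -> "ClonotypeTable":
        sub = self.data[self.data["sample_id"] == sample_id]
        return ClonotypeTable(
            sub.reset_index(drop=True),
            total_reads={sample_id: self.total_reads.get(sample_id, 0)},
        )

    def keys(self) -> set[tuple]:
        return set(map(tuple, self.data[list(KEY_COLUMNS)].to_numpy()))

    def __len__(self) -> int:
        return len(self.data)


def load_clonotypes(source) -> ClonotypeTable:
    """Load an AIRR-style TSV (or an equivalent DataFrame).

    Unproductive rows are removed, gene calls normalized to gene level,
    and duplicate within-sample keys aggregated by read sum.  Frequencies
    are computed here, against each sample's total productive reads.
    """
    if isinstance(source, pd.DataFrame):
        raw = source.copy()
    else:
        raw = pd.read_csv(source, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    raw["productive"] = _parse_productive(raw["productive"])
    prod = raw[raw["productive"]].copy()
    if prod.empty:
        warnings.warn("no productive clonotypes in input", stacklevel=2)
    prod["v_gene"] = prod["v_call"].map(normalize_gene)
    prod["j_gene"] = prod["j_call"].map(normalize_gene)
    prod["duplicate_count"] = prod["duplicate_count"].astype(int)
    if (prod["duplicate_count"] < 1).any():
        raise SchemaError("duplicate_count must be >= 1")

    group_cols = ["sample_id", "v_gene", "junction", "j_gene"]
    agg = {
        "duplicate_count": "sum",
        "junction_aa": "first",
        "v_call": "first",
        "j_call": "first",
    }
    if "subset" in prod.columns:
        agg["subset"] = "first"
    data = (
        prod.groupby(group_cols, as_index=False, sort=False).agg(agg)
        if len(prod)
        else prod.reindex(columns=group_cols + list(agg))
    )
    totals = data.groupby("sample_id")["duplicate_count"].sum().astype(int)
    data["frequency"] = data["duplicate_count"] / data["sample_id"].map(totals)
    return ClonotypeTable(data.reset_index(drop=True), totals.to_dict())


def filter_low_reads(table: ClonotypeTable, min_reads: int = 50) -> ClonotypeTable:
    """Drop likely sequencing artifacts: clonotypes below ``min_reads``.

    Strictly-below semantics: a clonotype with exactly ``min_reads`` reads
    is retained.  Frequencies are not recomputed (they keep the full
    pre-filter library denominator).
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    keep = table.data["duplicate_count"] >= min_reads
    return ClonotypeTable(
        table.data[keep].reset_index(drop=True), dict(table.total_reads)
    )


def shannon_diversity(table: ClonotypeTable, sample_id: str | None = None) -> float:
    """Shannon diversity H = -sum p ln p over clonotype frequencies.

    Frequencies are renormalized over the rows present so the index is
    well defined after filtering.  Undefined (NaN) for an empty table.
    """
    data = table.data
    if sample_id is not None:
        data = data[data["sample_id"] == sample_id]
    counts = data["duplicate_count"].to_numpy(dtype=float)
    if counts.size == 0 or counts.sum() == 0:
        return float("nan")
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() + 0.0)  # +0.0 normalizes -0.0


def cdr3_spectrum(
    table: ClonotypeTable, top_n: int = 50, sample_id: str | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CDR3 length spectrum with the top clonotypes annotated.

    Returns ``(spectrum, top)``: the per-amino-acid-length read-mass
    distribution, and the ``top_n`` most frequent clonotypes with their
    rank (1 = most frequent) and length.  ``top_n=0`` yields an empty
    annotation table.
    """
    data = table.data
    if sample_id is not None:
        data = data[data["sample_id"] == sample_id]
    data = data.assign(cdr3_length=data["junction_aa"].astype(str).str.len())
    total = data["duplicate_count"].sum()
    spectrum = (
        data.groupby("cdr3_length")["duplicate_count"].sum() / total
    ).rename("mass").reset_index()
    top = (
        data.sort_values("duplicate_count", ascending=False, kind="stable")
        .head(top_n)
        .copy()
    )
    top["rank"] = np.arange(1, len(top) + 1)
    return spectrum, top.reset_index(drop=True)


@dataclass
class OverlapResult:
    """Clonotypes shared by every listed sample (after read filtering).

    ``table`` has one row per shared key with per-sample frequency,
    read-count and top-50-rank columns.
    """

    samples: tuple[str, ...]
    table: pd.DataFrame

    @property
    def shared_keys(self) -> set[tuple]:
        return set(map(tuple, self.table[list(KEY_COLUMNS)].to_numpy()))

    def __len__(self) -> int:
        return len(self.table)


def overlap_clonotypes(
    tables: list[ClonotypeTable], min_reads: int = 50, top_n: int = 50
) -> OverlapResult:
    """Intersect >=2 samples on the within-study clonotype key.

    Each sample is filtered to clonotypes with at least ``min_reads``
    reads before intersecting, so a clone must clear the artifact filter
    in every sample to count as shared.
    """
    flat: list[ClonotypeTable] = []
    for t in tables:
        for s in t.samples:
            flat.append(t.sample(s))
    if len(flat) < 2:
        raise ValueError("overlap requires at least two samples")
    sample_ids = tuple(t.samples[0] for t in flat)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids in overlap input")

    filtered = [filter_low_reads(t, min_reads) for t in flat]
    shared = set.intersection(*(t.keys() for t in filtered))
    rows = []
    for key in shared:
        row = dict(zip(KEY_COLUMNS, key))
        for sid, t in zip(sample_ids, filtered):
            d = t.data
            hit = d[
                (d["v_gene"] == key[0])
                & (d["junction"] == key[1])
                & (d["j_gene"] == key[2])
            ].iloc[0]
            ranks = (
                t.data.sort_values(
                    "duplicate_count", ascending=False, kind="stable"
                ).head(top_n)[list(KEY_COLUMNS)]
            )
            in_top = (ranks.to_numpy() == np.array(key, dtype=object)).all(1)
            row[f"{sid}_frequency"] = float(hit["frequency"])
            row[f"{sid}_reads"] = int(hit["duplicate_count"])
            row[f"{sid}_top{top_n}_rank"] = (
                int(np.flatnonzero(in_top)[0]) + 1 if in_top.any() else None
            )
            row["junction_aa"] = hit["junction_aa"]
        rows.append(row)
    cols = list(KEY_COLUMNS) + ["junction_aa"] + [
        f"{sid}_{suffix}"
        for sid in sample_ids
        for suffix in ("frequency", "reads", f"top{top_n}_rank")
    ]
    table = pd.DataFrame(rows, columns=cols)
    if len(table):
        table = table.sort_values(
            list(KEY_COLUMNS), kind="stable"
        ).reset_index(drop=True)
    return OverlapResult(samples=sample_ids, table=table)


def hla_compatible(query: str | None, restriction: str) -> bool:
    """HLA compatibility at the resolution of the less specific call.

    'HLA-A*02' is compatible with 'HLA-A*02:01'; an unspecified query
    matches anything.
    """
    if query is None or str(query).strip() == "":
        return True
    q = str(query).strip().upper().rstrip(":")
    r = str(restriction).strip().upper().rstrip(":")
    fields_q = q.replace("*", ":").split(":")
    fields_r = r.replace("*", ":").split(":")
    depth = min(len(fields_q), len(fields_r))
    return fields_q[:depth] == fields_r[:depth]


REFERENCE_COLUMNS = ("v_call", "cdr3_aa", "j_call", "hla", "antigen")


def match_antigen_db(
    table: ClonotypeTable,
    reference: pd.DataFrame,
    hla: str | None = None,
) -> pd.DataFrame:
    """Annotate clonotypes found in an antigen-specificity reference.

    A match requires equal V gene, amino-acid junction and J gene
    (allele-stripped), and — when ``hla`` is given — a compatible HLA
    restriction.  Returns matched rows with the reference's antigen and
    restriction columns appended.
    """
    missing = [c for c in REFERENCE_COLUMNS if c not in reference.columns]
    if missing:
        raise SchemaError(
            f"reference missing column(s): {', '.join(missing)}"
        )
    ref = reference.copy()
    ref["v_gene"] = ref["v_call"].map(normalize_gene)
    ref["j_gene"] = ref["j_call"].map(normalize_gene)
    if hla is not None:
        ref = ref[[hla_compatible(hla, r) for r in ref["hla"]]]
    merged = table.data.merge(
        ref[["v_gene", "cdr3_aa", "j_gene", "hla", "antigen"]],
        left_on=["v_gene", "junction_aa", "j_gene"],
        right_on=["v_gene", "cdr3_aa", "j_gene"],
        how="inner",
    )
    return merged.drop(columns=["cdr3_aa"]).reset_index(drop=True)
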