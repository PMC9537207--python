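"""Synthetic multi-tube cytometry samples and TRB clonotype tables.

The generator plants a known clonal and phenotypic structure — naive,
early-memory and late-memory populations, Vbeta-restricted clonal spikes
with homogeneous TIGIT/PD-1 phenotypes, and clonotypes shared across
samples — so every downstream stage can be scored against ground truth
without any external data.

Intensities are drawn log-normally per marker per population (cytometry
fluorescence is right-skewed), parameterized on the raw (pre-arcsinh)
scale by a mean and standard deviation.  Marker defaults are synthetic:
they are chosen to give realistic arcsinh-scale separation between
positive and negative populations, not fitted to any instrument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ._rng import stream_rng as _stream_rng
from .io import TubeEventMatrix, write_events
from .panel import VB_NEGATIVE, PanelDesign, generate_panel_design

__all__ = [
    "PopulationSpec",
    "GroundTruthManifest",
    "RepertoireSpec",
    "SyntheticConfigError",
    "reference_vb_distribution",
    "default_manifest",
    "simulate_sample",
    "export_gated_population_files",
    "simulate_repertoire",
    "simulate_repertoires",
    "clonotype_to_tsv",
]

#: Fraction of polyclonal repertoire mass outside antibody coverage
#: (the kit detects roughly 70% of the repertoire).
DEFAULT_UNDETECTED_MASS = 0.30

UNDETECTED = "undetected"

# Raw-scale intensity defaults (arbitrary fluorescence units).
POS_MEAN, POS_SD = 5000.0, 2000.0
NEG_MEAN, NEG_SD = 80.0, 40.0
HIGH_MEAN, HIGH_SD = 20000.0, 6000.0  # e.g. CD3-high gamma-delta surrogate
SCATTER_MEAN = {"FSC-A": 50000.0, "SSC-A": 20000.0}
SCATTER_SD = {"FSC-A": 12000.0, "SSC-A": 6000.0}


class SyntheticConfigError(ValueError):
    """Inconsistent generator configuration."""


def _lognormal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Log-normal draws moment-matched to the given raw-scale mean and sd."""
    if mean <= 0:
        raise SyntheticConfigError("log-normal mean must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


@dataclass
class PopulationSpec:
    """One planted T-cell population.

    ``vb_distribution`` is either a dict of per-family frequencies (a
    polyclonal population; mass not assigned to any family is repertoire
    outside antibody coverage) or a single family label / ``"undetected"``
    (a clonal population).
    """

    name: str
    subset: str  # naive | early_memory | late_memory_CD4 | late_memory_CD8 | double_negative
    fraction: float
    marker_means: dict[str, float]
    marker_sds: dict[str, float]
    vb_distribution: dict[str, float] | str

    _SUBSETS = (
        "naive",
        "early_memory",
        "late_memory_CD4",
        "late_memory_CD8",
        "double_negative",
    )

    def __post_init__(self) -> None:
        if self.subset not in self._SUBSETS:
            raise SyntheticConfigError(f"unknown subset {self.subset!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise SyntheticConfigError("fraction must lie in [0, 1]")
        if isinstance(self.vb_distribution, dict):
            vals = np.array(list(self.vb_distribution.values()), dtype=float)
            if (vals < 0).any():
                raise SyntheticConfigError("Vbeta frequencies must be >= 0")
            if vals.sum() > 1.0 + 1e-9:
                raise SyntheticConfigError(
                    "polyclonal Vbeta frequencies exceed 1"
                )

    @property
    def is_clonal(self) -> bool:
        return isinstance(self.vb_distribution, str)

    def draw_families(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.is_clonal:
            return np.full(n, self.vb_distribution, dtype=object)
        fams = list(self.vb_distribution) + [UNDETECTED]
        probs = np.array(list(self.vb_distribution.values()), dtype=float)
        probs = np.append(probs, max(0.0, 1.0 - probs.sum()))
        probs /= probs.sum()
        return rng.choice(np.array(fams, dtype=object), size=n, p=probs)


@dataclass
class GroundTruthManifest:
    """Planted populations plus bookkeeping for recovery scoring."""

    populations: list[PopulationSpec]
    seed: int
    planted_shared_clonotypes: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(p.fraction for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise SyntheticConfigError(
                f"population fractions sum to {total}, expected 1"
            )
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise SyntheticConfigError("population names must be unique")


def _phenotype(
    positive: tuple[str, ...],
    high: tuple[str, ...] = (),
    backbone: tuple[str, ...] = (
        "CD3", "CD4", "CD8", "CCR7", "CD45RA", "CD27", "CD28", "TIGIT", "PD-1",
    ),
) -> tuple[dict[str, float], dict[str, float]]:
    means, sds = {}, {}
    for m in backbone:
        if m in high:
            means[m], sds[m] = HIGH_MEAN, HIGH_SD
        elif m in positive:
            means[m], sds[m] = POS_MEAN, POS_SD
        else:
            means[m], sds[m] = NEG_MEAN, NEG_SD
    for ch, mu in SCATTER_MEAN.items():
        means[ch], sds[ch] = mu, SCATTER_SD[ch]
    return means, sds


def _polyclonal(families: tuple[str, ...],
                undetected_mass: float = DEFAULT_UNDETECTED_MASS) -> dict[str, float]:
    """Uniform polyclonal distribution (each detected family equal)."""
    per = (1.0 - undetected_mass) / len(families)
    return {f: per for f in families}


def reference_vb_distribution(
    families: tuple[str, ...],
    undetected_mass: float = DEFAULT_UNDETECTED_MASS,
    decay: float = 0.12,
) -> dict[str, float]:
    """Skewed polyclonal Vbeta usage shared by all diverse populations.

    Healthy Vbeta family usage is far from uniform (frequencies span
    roughly 0.5-9% of T cells) and the same skew recurs across subsets of
    one individual; an exponentially decaying weight over families
    emulates that.  Sharing this base across polyclonal populations is
    what lets a correlation-based comparison recognize "naive-like"
    profiles.
    """
    w = np.exp(-decay * np.arange(len(families)))
    w = w / w.sum() * (1.0 - undetected_mass)
    return dict(zip(families, w.tolist()))


def default_manifest(
    seed: int = 0,
    panel: PanelDesign | None = None,
    undetected_mass: float = DEFAULT_UNDETECTED_MASS,
    gamma_delta_fraction: float = 0.02,
) -> GroundTruthManifest:
    """Study-like mixture: diverse naive/early-memory compartments, a
    polyclonal late-memory background, three clonal late-memory spikes
    (one outside antibody coverage) and a small CD4-CD3high contaminant.
    """
    if panel is None:
        panel = generate_panel_design()
    fams = panel.families
    poly = reference_vb_distribution(fams, undetected_mass)

    def pop(name, subset, fraction, positive, vb, high=()):
        means, sds = _phenotype(tuple(positive), tuple(high))
        return PopulationSpec(name, subset, fraction, means, sds, vb)

    pops = [
        pop("naive_CD4", "naive", 0.25,
            ("CD3", "CD4", "CCR7", "CD45RA", "CD27", "CD28"), dict(poly)),
        pop("naive_CD8", "naive", 0.15,
            ("CD3", "CD8", "CCR7", "CD45RA", "CD27", "CD28"), dict(poly)),
        pop("early_memory_CD4", "early_memory", 0.12,
            ("CD3", "CD4", "CD27", "CD28"), dict(poly)),
        pop("early_memory_CD8", "early_memory", 0.08,
            ("CD3", "CD8", "CD27", "CD28"), dict(poly)),
        pop("late_memory_CD4_poly", "late_memory_CD4", 0.10,
            ("CD3", "CD4"), dict(poly)),
        pop("late_memory_CD8_poly", "late_memory_CD8", 0.10,
            ("CD3", "CD8"), dict(poly)),
        # Clonal late-memory spikes, each with a homogeneous TIGIT/PD-1
        # phenotype distinct from the polyclonal late-memory background.
        pop("clone_CD4_Vb13.2", "late_memory_CD4", 0.08,
            ("CD3", "CD4", "PD-1"), "Vb13.2"),
        pop("clone_CD8_Vb12", "late_memory_CD8", 0.07,
            ("CD3", "CD8", "TIGIT", "CD45RA"), "Vb12"),
        pop("clone_CD8_uncovered", "late_memory_CD8", 0.03,
            ("CD3", "CD8", "PD-1"), UNDETECTED),
        pop("gamma_delta_like", "double_negative", gamma_delta_fraction,
            (), UNDETECTED, high=("CD3",)),
    ]
    # absorb any leftover mass into the naive CD4 compartment
    pops[0].fraction += 1.0 - sum(p.fraction for p in pops)
    return GroundTruthManifest(populations=pops, seed=seed)


def simulate_sample(
    manifest: GroundTruthManifest,
    panel: PanelDesign,
    events_per_tube: int,
    seed: int | None = None,
    sample_id: str = "S1",
    timepoint: str | None = None,
) -> list[TubeEventMatrix]:
    """Draw one sample's per-tube event matrices with ground-truth labels.

    Every tube draws from the same population mixture via its own RNG
    stream.  An event carries a Vbeta-positive gate label only when its
    true family is among that tube's three antibodies; otherwise ``Vb-``.
    Ground truth (population, true family) rides along in ``tube.truth``.
    """
    if events_per_tube < 100:
        raise SyntheticConfigError("events_per_tube must be >= 100")
    seed = manifest.seed if seed is None else seed

    pops: list[PopulationSpec] = []
    for p in manifest.populations:
        if p.fraction == 0.0:
            if p.is_clonal:
                warnings.warn(
                    f"clonal population {p.name!r} has zero fraction; skipped",
                    stacklevel=2,
                )
            continue
        pops.append(p)
    fractions = np.array([p.fraction for p in pops], dtype=float)
    fractions /= fractions.sum()

    tubes: list[TubeEventMatrix] = []
    for tube_spec in panel.tubes:
        rng = _stream_rng(seed, sample_id, tube_spec.tube_id)
        pop_idx = rng.choice(len(pops), size=events_per_tube, p=fractions)
        channels = panel.event_channels(tube_spec.tube_id)
        data = np.empty((events_per_tube, len(channels)), dtype=float)
        families = np.empty(events_per_tube, dtype=object)
        pop_names = np.empty(events_per_tube, dtype=object)
        for i, p in enumerate(pops):
            mask = pop_idx == i
            n = int(mask.sum())
            if n == 0:
                continue
            pop_names[mask] = p.name
            families[mask] = p.draw_families(rng, n)
            for j, ch in enumerate(channels):
                if ch.startswith("TCR_"):
                    continue  # filled below
                data[mask, j] = _lognormal(
                    rng, p.marker_means[ch], p.marker_sds[ch], n
                )
        # Vbeta channels: bright in the event's own family channel (when the
        # tube carries that antibody), background otherwise.
        for j, ch in enumerate(channels):
            if not ch.startswith("TCR_"):
                continue
            data[:, j] = _lognormal(rng, NEG_MEAN, NEG_SD, events_per_tube)
            fam = ch[len("TCR_"):]
            hit = families == fam
            n_hit = int(hit.sum())
            if n_hit:
                data[hit, j] = _lognormal(rng, POS_MEAN, POS_SD, n_hit)
        in_tube = np.isin(families.astype(str), tube_spec.vb_families)
        gates = np.where(in_tube, families, VB_NEGATIVE)
        tubes.append(
            TubeEventMatrix(
                tube_id=tube_spec.tube_id,
                sample_id=sample_id,
                timepoint=timepoint,
                data=pd.DataFrame(data, columns=list(channels)),
                gate_labels=pd.Series(gates.astype(object), name="vb_gate"),
                truth=pd.DataFrame(
                    {"population": pop_names, "true_vb": families.astype(str)}
                ),
            )
        )
    return tubes


def export_gated_population_files(
    samples: dict[str, list[TubeEventMatrix]], outdir
) -> list[Path]:
    """Write one event CSV per (sample, tube, gated population).

    Each tube yields four files: its three Vbeta-positive gates and the
    Vbeta-negative remainder — 4 samples x 8 tubes x 4 gates = 128 files.
    A sidecar TSV manifest with per-event ground truth is written per tube.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for sample_id, tubes in samples.items():
        for tube in tubes:
            if tube.gate_labels is None:
                raise ValueError(f"tube {tube.tube_id} has no gate labels")
            # deterministic file order: the tube's three families, then Vb-
            order = [*_tube_family_order(tube), VB_NEGATIVE]
            for gate in order:
                mask = (tube.gate_labels == gate).to_numpy()
                sub = TubeEventMatrix(
                    tube_id=tube.tube_id,
                    sample_id=sample_id,
                    data=tube.data.loc[mask].reset_index(drop=True),
                    gate_labels=tube.gate_labels.loc[mask].reset_index(drop=True),
                )
                safe = gate.replace("-", "neg").replace(".", "_")
                path = outdir / f"{sample_id}_{tube.tube_id}_{safe}.csv"
                write_events(sub, path)
                paths.append(path)
            if tube.truth is not None:
                truth = tube.truth.copy()
                truth.insert(0, "event_index", np.arange(len(truth)))
                truth.insert(0, "tube_id", tube.tube_id)
                truth.insert(0, "sample_id", sample_id)
                truth.to_csv(
                    outdir / f"{sample_id}_{tube.tube_id}_truth.tsv",
                    sep="\t", index=False,
                )
    return paths


def _tube_family_order(tube: TubeEventMatrix) -> list[str]:
    fams = [c[len("TCR_"):] for c in tube.data.columns if c.startswith("TCR_")]
    return fams


# ---------------------------------------------------------------------------
# TRB clonotype tables
# ---------------------------------------------------------------------------

_CODONS = [
    a + b + c
    for a in "TCAG"
    for b in "TCAG"
    for c in "TCAG"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass
class RepertoireSpec:
    """Recipe for one sample's TRB clonotype table.

    ``clone_size_distribution`` is ``"uniform"``, ``("geometric", p)`` or
    ``("spiked", [top-clone fractions])`` — spiked fractions are exact
    read shares for the top clones, the remainder spread uniformly.
    ``shared_with`` lists ``(other_sample_id, n_shared, frequency)``
    sharing plans honoured by :func:`simulate_repertoires`.
    """

    sample_id: str
    n_clonotypes: int
    total_reads: int
    clone_size_distribution: str | tuple = "uniform"
    unproductive_fraction: float = 0.0
    subset: str = ""
    shared_with: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.total_reads < self.n_clonotypes:
            raise SyntheticConfigError("total_reads must be >= n_clonotypes")
        if not 0.0 <= self.unproductive_fraction < 1.0:
            raise SyntheticConfigError("unproductive_fraction must be in [0, 1)")
        dist = self.clone_size_distribution
        if isinstance(dist, tuple) and dist[0] == "spiked":
            if sum(dist[1]) >= 1.0:
                raise SyntheticConfigError("spiked fractions must sum to < 1")


def _random_clonotype(rng: np.random.Generator) -> dict:
    """One random clonotype: gene calls plus an in-frame CDR3 junction."""
    n_codons = int(rng.integers(7, 21))  # 21-60 nt in steps of 3
    codons = rng.choice(_CODONS, size=n_codons - 1)
    junction = "TGC" + "".join(codons)  # canonical cysteine start
    return {
        "v_call": f"TRBV{int(rng.integers(1, 31))}*01",
        "junction": junction,
        "junction_aa": str(Seq(junction).translate()),
        "j_call": f"TRBJ{int(rng.integers(1, 3))}-{int(rng.integers(1, 7))}*01",
    }


def _expected_fractions(spec: RepertoireSpec, n_free: int) -> np.ndarray:
    dist = spec.clone_size_distribution
    if dist == "uniform":
        w = np.ones(n_free)
    elif isinstance(dist, tuple) and dist[0] == "geometric":
        p = float(dist[1])
        w = (1 - p) ** np.arange(n_free) * p
    elif isinstance(dist, tuple) and dist[0] == "spiked":
        spikes = np.asarray(dist[1], dtype=float)
        w = np.full(n_free, (1.0 - spikes.sum()) / max(n_free - len(spikes), 1))
        w[: len(spikes)] = spikes
    else:
        raise SyntheticConfigError(
            f"unknown clone_size_distribution {dist!r}"
        )
    return w / w.sum()


def _largest_remainder(fracs: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer reads to fractions, exactly."""
    raw = fracs * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def simulate_repertoire(
    spec: RepertoireSpec,
    seed: int,
    planted: list[tuple[dict, float]] | None = None,
) -> pd.DataFrame:
    """Emit an AIRR-style clonotype table for one sample.

    ``planted`` entries ``(clonotype, frequency)`` appear verbatim with a
    read count of at least ``round(frequency * total_reads)``.  Read counts
    are apportioned deterministically (largest remainder), so a spiked top
    clone's emitted frequency matches its specification to within one read.
    """
    rng = _stream_rng(seed, spec.sample_id, "repertoire")
    planted = planted or []
    if len(planted) > spec.n_clonotypes:
        raise SyntheticConfigError(
            "planted shared clonotypes exceed n_clonotypes"
        )

    n_unprod_reads = int(round(spec.unproductive_fraction * spec.total_reads))
    n_prod_reads = spec.total_reads - n_unprod_reads

    planted_fracs = np.array([f for _, f in planted], dtype=float)
    if planted_fracs.sum() >= 1.0:
        raise SyntheticConfigError("planted frequencies must sum to < 1")
    planted_reads = np.maximum(
        1, np.round(planted_fracs * n_prod_reads).astype(int)
    ) if len(planted) else np.zeros(0, dtype=int)

    n_free = spec.n_clonotypes - len(planted)
    free_reads_total = n_prod_reads - int(planted_reads.sum())
    if n_free > 0:
        fracs = _expected_fractions(spec, n_free)
        free_reads = _largest_remainder(fracs, free_reads_total)
        free_reads = np.maximum(free_reads, 1)
    else:
        free_reads = np.zeros(0, dtype=int)

    rows: list[dict] = []
    seen_junctions = {c["junction"] for c, _ in planted}
    for (clono, _), reads in zip(planted, planted_reads):
        rows.append({**clono, "duplicate_count": int(reads), "productive": True})
    for reads in free_reads:
        clono = _random_clonotype(rng)
        while clono["junction"] in seen_junctions:
            clono = _random_clonotype(rng)
        seen_junctions.add(clono["junction"])
        rows.append({**clono, "duplicate_count": int(reads), "productive": True})

    if n_unprod_reads > 0:
        n_unprod_clones = max(1, spec.n_clonotypes // 10)
        counts = _largest_remainder(
            np.full(n_unprod_clones, 1.0 / n_unprod_clones), n_unprod_reads
        )
        for reads in counts[counts > 0]:
            clono = _random_clonotype(rng)
            junction = clono["junction"][:-1]  # frameshift: out-of-frame length
            rows.append({
                "v_call": clono["v_call"],
                "junction": junction,
                "junction_aa": "",
                "j_call": clono["j_call"],
                "duplicate_count": int(reads),
                "productive": False,
            })

    table = pd.DataFrame(rows)
    table.insert(0, "sample_id", spec.sample_id)
    table.insert(1, "subset", spec.subset)
    return table


def simulate_repertoires(
    specs: list[RepertoireSpec], seed: int
) -> tuple[dict[str, pd.DataFrame], list[dict]]:
    """Simulate linked samples, planting the shared clonotypes each spec
    requests.  Returns the tables and the planted shared clonotype keys.
    """
    by_id = {s.sample_id: s for s in specs}
    planted: dict[str, list[tuple[dict, float]]] = {s.sample_id: [] for s in specs}
    shared_keys: list[dict] = []
    done: set[tuple[str, str]] = set()
    for s in specs:
        for other, n_shared, freq in s.shared_with:
            pair = tuple(sorted((s.sample_id, other)))
            if pair in done:
                continue
            done.add(pair)
            if other not in by_id:
                raise SyntheticConfigError(f"unknown partner sample {other!r}")
            if n_shared > min(s.n_clonotypes, by_id[other].n_clonotypes):
                raise SyntheticConfigError(
                    "shared clonotypes exceed n_clonotypes of a partner"
                )
            rng = _stream_rng(seed, *pair, "shared")
            for _ in range(n_shared):
                clono = _random_clonotype(rng)
                planted[s.sample_id].append((clono, freq))
                planted[other].append((clono, freq))
                shared_keys.append(
                    {**clono, "samples": list(pair), "frequency": freq}
                )
    tables = {
        s.sample_id: simulate_repertoire(s, seed, planted[s.sample_id])
        for s in specs
    }
    return tables, shared_keys


def clonotype_to_tsv(table: pd.DataFrame, path) -> None:
    """Write a clonotype table as AIRR-style TSV (productive as T/F)."""
    out = table.copy()
    out["productive"] = np.where(out["productive"].astype(bool), "T", "F")
    out.to_csv(path, sep="\t", index=False)
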