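"""End-to-end orchestration with a config file and deterministic outputs.

``run_pipeline`` executes simulate (optional) -> read/gate -> preprocess
-> cluster -> Vbeta statistics -> repertoire, writing TSV tables and a
machine-readable run manifest (package version, seeds, parameters, input
checksums, config hash).  Identical config + seed reproduce identical
tables byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import stream_seed
from .cluster import assign_subsets, som_cluster
from .io import GateSpec, apply_gates, read_events
from .panel import PanelDesign, generate_panel_design
from .preprocess import (
    DEFAULT_COFACTOR,
    GammaDeltaExclusion,
    arcsinh_transform,
    pool_tubes,
    proportional_downsample,
    scatter_normalize,
)
from .repertoire import (
    filter_low_reads,
    load_clonotypes,
    overlap_clonotypes,
    shannon_diversity,
)
from .synthetic import (
    RepertoireSpec,
    default_manifest,
    simulate_repertoires,
    simulate_sample,
)
from .vb_stats import (
    call_expansions,
    cluster_vb_profile,
    event_subset_labels,
    expansion_kinetics,
    inverse_simpson,
    kinetics_to_tsv,
    subset_vb_distribution,
)

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "load_config"]

log = logging.getLogger("vbflow")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """All parameters of one pipeline run.

    With ``simulate=True`` the synthetic generator provides the inputs;
    otherwise ``samples`` must map sample id -> {tube id -> event CSV}.
    Every stochastic stage derives its stream from ``seed``.
    """

    outdir: str = "vbflow_out"
    seed: int = 0
    simulate: bool = True
    panel_path: str | None = None
    samples: dict[str, dict[str, str]] = field(default_factory=dict)
    sample_ids: list[str] = field(
        default_factory=lambda: ["pre_boost", "post_2005", "post_2018", "donor"]
    )
    events_per_tube: int = 2000
    cofactor: float = DEFAULT_COFACTOR
    gate_threshold_raw: float = 1000.0  # Vbeta positivity cutoff, raw scale
    exclude_gamma_delta: bool = True
    grid: tuple[int, int] = (10, 10)
    n_metaclusters: int = 10
    delta: float = 0.5  # dominance threshold for expansion calls
    tau: float = 0.8  # naive-clade similarity threshold
    naive_reference_sample: str | None = None
    min_reads: int = 50
    top_n: int = 50
    repertoire_total_reads: int = 50_000
    repertoire_n_clonotypes: int = 400
    plots: bool = False

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        params = asdict(self)
        params.pop("outdir")
        payload = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(str(path), encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    known = RunConfig.__dataclass_fields__
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig(**data)
    if isinstance(cfg.grid, list):
        cfg.grid = tuple(cfg.grid)
    return cfg


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# vbflow config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _acquire_tubes(config: RunConfig, panel: PanelDesign) -> dict[str, list]:
    """Simulate or read every sample's tubes (ungated intensities)."""
    samples: dict[str, list] = {}
    checksums: dict[str, str] = {}
    if config.simulate:
        manifest = default_manifest(seed=config.seed, panel=panel)
        for sid in config.sample_ids:
            samples[sid] = simulate_sample(
                manifest, panel, config.events_per_tube,
                seed=config.seed, sample_id=sid, timepoint=sid,
            )
    else:
        if not config.samples:
            raise ConfigError("simulate=false requires a samples mapping")
        for sid, tubes in config.samples.items():
            samples[sid] = []
            for tube_id, path in tubes.items():
                p = Path(path)
                if not p.exists():
                    raise ConfigError(f"event file not found: {p}")
                checksums[str(p)] = _checksum(p)
                samples[sid].append(
                    read_events(p, panel, tube_id=tube_id, sample_id=sid)
                )
    _acquire_tubes.checksums = checksums  # type: ignore[attr-defined]
    return samples


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle.

    Returns a summary dict (also written as ``run_manifest.json``).
    Stage failures surface as exceptions named after the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    log.info("run start (config hash %s)", cfg_hash)

    # -- panel -------------------------------------------------------------
    if config.panel_path:
        p = Path(config.panel_path)
        if not p.exists():
            raise ConfigError(f"panel file not found: {p}")
        panel = PanelDesign.from_file(p)
    else:
        panel = generate_panel_design()

    # -- acquire + gate ----------------------------------------------------
    samples = _acquire_tubes(config, panel)
    thr_post = float(np.arcsinh(config.gate_threshold_raw / config.cofactor))
    all_tubes = []
    for sid, tubes in samples.items():
        processed = []
        for tube in tubes:
            fluor = [c for c in tube.data.columns
                     if c not in panel.scatter_channels]
            tube.data = arcsinh_transform(tube.data, config.cofactor, fluor)
            tube.data = scatter_normalize(tube.data, panel.scatter_channels)
            gates = GateSpec(
                thresholds={
                    ch: thr_post for ch in panel.tube(tube.tube_id).vb_channels
                }
            )
            processed.append(apply_gates(tube, gates, panel))
        processed = proportional_downsample(
            processed, seed=stream_seed(config.seed, sid, "ds") % 2**31
        )
        all_tubes.extend(processed)

    pooled = pool_tubes(
        all_tubes, panel,
        exclusion=GammaDeltaExclusion() if config.exclude_gamma_delta else None,
    )
    _write(pooled.excluded, outdir / "exclusion_report.tsv", cfg_hash)

    # -- cluster + subsets -------------------------------------------------
    clusters = som_cluster(
        pooled, grid=config.grid, n_metaclusters=config.n_metaclusters,
        seed=config.seed,
    )
    assignment = assign_subsets(clusters)
    subset_of_event = event_subset_labels(clusters, assignment)
    _write(
        clusters.medians.round(4).reset_index(),
        outdir / "cluster_medians.tsv", cfg_hash,
    )
    _write(
        pd.DataFrame(
            {
                "cluster": list(assignment.labels),
                "subset": [assignment.labels[k] for k in assignment.labels],
                "lineage": [assignment.lineage[k] for k in assignment.labels],
                "flag": [assignment.flags.get(k, "") for k in assignment.labels],
            }
        ),
        outdir / "cluster_subsets.tsv", cfg_hash,
    )

    # -- Vbeta statistics ---------------------------------------------------
    subset_rows, diversity_rows = [], []
    subset_scopes = sorted(set(assignment.labels.values()))
    for sid in samples:
        for scope in subset_scopes:
            try:
                prof = subset_vb_distribution(
                    pooled, subset_of_event, scope, sample_id=sid
                )
            except ValueError:
                continue
            div = inverse_simpson(prof)
            diversity_rows.append(
                {
                    "sample_id": sid, "subset": scope,
                    "inverse_simpson": div.inverse_simpson,
                    "n_vb_pos_total": div.n_vb_pos_total,
                }
            )
            t = prof.table.reset_index()
            t.insert(0, "sample_id", sid)
            t.insert(1, "subset", scope)
            subset_rows.append(t)
    _write(pd.concat(subset_rows, ignore_index=True),
           outdir / "vb_subset_profiles.tsv", cfg_hash)
    _write(pd.DataFrame(diversity_rows), outdir / "vb_diversity.tsv", cfg_hash)

    # -- expansion calls per lineage, tracked across samples ---------------
    ref_sample = config.naive_reference_sample or list(samples)[-1]
    kinetics_frames = []
    call_rows = []
    for lin in ("CD4", "CD8"):
        lm_clusters = [
            k for k, lab in assignment.labels.items()
            if lab == "late_memory" and assignment.lineage[k] == lin
        ]
        if not lm_clusters:
            continue
        try:
            naive_ref = subset_vb_distribution(
                pooled,
                np.where(
                    np.isin(clusters.labels,
                            [k for k in assignment.clusters_with_label("naive")
                             if assignment.lineage[k] == lin]),
                    "naive_ref", "other",
                ),
                "naive_ref", sample_id=ref_sample,
            )
        except ValueError:
            continue
        lm_mask = np.isin(clusters.labels, lm_clusters)
        from dataclasses import replace as _dc_replace

        from .vb_stats import vb_profile as _vb_profile

        # calls on cluster profiles pooled over samples (the heatmap view)
        profiles = {
            k: cluster_vb_profile(pooled, clusters, k) for k in lm_clusters
        }
        scope_prof = _vb_profile(
            pooled.meta.loc[lm_mask], panel, f"late_memory_{lin}"
        )
        calls = call_expansions(
            profiles, naive_ref,
            delta=config.delta, tau=config.tau,
            assignment=assignment, scope_profile=scope_prof,
        )
        for c in calls:
            call_rows.append(
                {
                    "lineage": lin,
                    "clusters": ",".join(map(str, c.clusters)),
                    "dominant_family": c.dominant_family,
                    "dominance": c.dominance,
                    "fingerprint": "/".join(c.fingerprint),
                    "naive_similarity": c.naive_similarity,
                    "total_frequency": c.total_frequency,
                }
            )
        # kinetics: re-express each call per timepoint
        calls_by_tp: dict[str, list] = {}
        for sid in samples:
            per_tp = []
            for c in calls:
                if c.dominant_family == "undetected":
                    continue
                fam = c.dominant_family
                cl_mask = np.isin(clusters.labels, list(c.clusters))
                m = pooled.meta
                sel = cl_mask & (m["sample_id"] == sid).to_numpy()
                n_pos = int((m.loc[sel, "vb_label"] == fam).sum())
                tube = panel.tube_of(fam)
                sc = lm_mask & (m["sample_id"] == sid).to_numpy()
                denom = int((m.loc[sc, "tube_id"] == tube).sum())
                if n_pos == 0 or denom == 0:
                    continue  # absent at this timepoint -> ND
                per_tp.append(
                    _dc_replace(
                        c, total_frequency=n_pos / denom, timepoint=sid
                    )
                )
            calls_by_tp[sid] = per_tp
        if calls and calls_by_tp:
            kin = expansion_kinetics(calls_by_tp)
            kin.insert(0, "lineage", lin)
            kinetics_frames.append(kin)
    _write(
        pd.DataFrame(
            call_rows,
            columns=["lineage", "clusters", "dominant_family", "dominance",
                     "fingerprint", "naive_similarity", "total_frequency"],
        ),
        outdir / "expansion_calls.tsv", cfg_hash,
    )
    if kinetics_frames:
        kin_all = pd.concat(kinetics_frames, ignore_index=True)
        with open(outdir / "expansion_kinetics.tsv", "w", encoding="utf-8") as fh:
            fh.write(f"# vbflow config_hash={cfg_hash}\n")
        kinetics_to_tsv_append(kin_all, outdir / "expansion_kinetics.tsv")

    # -- repertoire stage (synthetic companion tables) ----------------------
    rep_specs = [
        RepertoireSpec(
            sample_id="blood_memory_CD4", subset="memory_CD4",
            n_clonotypes=config.repertoire_n_clonotypes,
            total_reads=config.repertoire_total_reads,
            clone_size_distribution=("spiked", [0.15, 0.08, 0.05]),
            unproductive_fraction=0.05,
            shared_with=[("skin_wart", 5, 0.01)],
        ),
        RepertoireSpec(
            sample_id="skin_wart", subset="skin",
            n_clonotypes=config.repertoire_n_clonotypes,
            total_reads=config.repertoire_total_reads,
            clone_size_distribution=("geometric", 0.02),
            unproductive_fraction=0.05,
        ),
    ]
    tables, shared = simulate_repertoires(
        rep_specs, seed=stream_seed(config.seed, "repertoire") % 2**31
    )
    rep_rows = []
    loaded = {sid: load_clonotypes(tbl) for sid, tbl in tables.items()}
    for sid, tbl in loaded.items():
        filt = filter_low_reads(tbl, config.min_reads)
        rep_rows.append(
            {
                "sample_id": sid,
                "n_clonotypes": len(tbl),
                "n_after_filter": len(filt),
                "shannon": shannon_diversity(tbl),
            }
        )
    overlap = overlap_clonotypes(
        list(loaded.values()), min_reads=config.min_reads, top_n=config.top_n
    )
    _write(pd.DataFrame(rep_rows), outdir / "repertoire_summary.tsv", cfg_hash)
    _write(overlap.table, outdir / "clonotype_overlap.tsv", cfg_hash)

    if config.plots:
        from .plots import expansion_heatmap, vb_polar_plot

        first = list(samples)[0]
        prof = subset_vb_distribution(
            pooled, subset_of_event, subset_scopes[0], sample_id=first
        )
        vb_polar_plot(prof, outdir / "vb_polar.png")
        expansion_heatmap(
            {
                k: cluster_vb_profile(pooled, clusters, k)
                for k in clusters.cluster_ids
            },
            outdir / "vb_heatmap.png",
        )

    manifest = {
        "vbflow_version": __version__,
        "config_hash": cfg_hash,
        "config": asdict(config),
        "seed": config.seed,
        "n_pooled_events": pooled.n_events,
        "n_clusters": len(clusters.cluster_ids),
        "n_expansion_calls": len(call_rows),
        "n_shared_clonotypes": len(overlap),
        "planted_shared_clonotypes": len(shared),
        "input_checksums": getattr(_acquire_tubes, "checksums", {}),
    }
    with open(outdir / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    log.info("run complete: %d pooled events, %d expansion calls",
             pooled.n_events, len(call_rows))
    return manifest


def kinetics_to_tsv_append(kinetics: pd.DataFrame, path: Path) -> None:
    out = kinetics.copy()
    tp_cols = [
        c for c in out.columns
        if c not in ("lineage", "dominant_family", "fingerprint")
    ]
    for c in tp_cols:
        out[c] = out[c].map(
            lambda v: "ND" if pd.isna(v) else f"{float(v):.6g}"
        )
    out.to_csv(path, sep="\t", index=False, mode="a")
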