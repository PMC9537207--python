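"""Shared fixtures: a small panel, simulated samples, and a pooled matrix.

Everything is generated at test time from seeded synthetic data; the
session scope keeps the heavier simulation/clustering work to one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from vbflow import (
    GammaDeltaExclusion,
    GateSpec,
    apply_gates,
    arcsinh_transform,
    default_manifest,
    generate_panel_design,
    pool_tubes,
    proportional_downsample,
    scatter_normalize,
    simulate_sample,
    som_cluster,
)
from vbflow.cluster import assign_subsets

SEED = 7
GATE_THRESHOLD_POST = float(np.arcsinh(1000.0 / 150.0))


@pytest.fixture(scope="session")
def panel():
    return generate_panel_design()


@pytest.fixture(scope="session")
def manifest(panel):
    return default_manifest(seed=SEED, panel=panel)


@pytest.fixture(scope="session")
def raw_tubes(manifest, panel):
    """One simulated sample, raw intensities + truth gate labels."""
    return simulate_sample(manifest, panel, 1000, seed=SEED, sample_id="S1")


def preprocess_tubes(tubes, panel, seed=SEED, regate=True):
    """Transform, (re)gate and downsample a list of tubes."""
    out = []
    for tube in tubes:
        t = type(tube)(
            tube_id=tube.tube_id,
            sample_id=tube.sample_id,
            data=tube.data.copy(),
            gate_labels=tube.gate_labels,
            timepoint=tube.timepoint,
            truth=tube.truth,
        )
        fluor = [c for c in t.data.columns if c not in panel.scatter_channels]
        t.data = arcsinh_transform(t.data, 150.0, fluor)
        t.data = scatter_normalize(t.data, panel.scatter_channels)
        if regate:
            gates = GateSpec(
                thresholds={
                    ch: GATE_THRESHOLD_POST
                    for ch in panel.tube(t.tube_id).vb_channels
                }
            )
            t = apply_gates(t, gates, panel)
        out.append(t)
    return proportional_downsample(out, seed=seed)


@pytest.fixture(scope="session")
def pooled(manifest, panel):
    """Two samples, preprocessed and pooled with gamma-delta exclusion."""
    tubes = []
    for sid in ("S1", "S2"):
        raw = simulate_sample(manifest, panel, 1000, seed=SEED, sample_id=sid)
        tubes.extend(preprocess_tubes(raw, panel))
    return pool_tubes(tubes, panel, exclusion=GammaDeltaExclusion())


@pytest.fixture(scope="session")
def clustered(pooled):
    clusters = som_cluster(pooled, n_metaclusters=10, seed=SEED)
    assignment = assign_subsets(clusters)
    return clusters, assignment
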