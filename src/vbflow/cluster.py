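"""Phenotype clustering of pooled events, blind to Vbeta and CD3.

A self-organizing map (batch training) compresses events onto a small
grid; map nodes are then metaclustered by average-linkage agglomeration
of their codebook vectors, in the style of FlowSOM.  Clustering and the
optional 2-D embedding use scatter plus backbone markers excluding CD3 —
and never the Vbeta channels — so gate labels cannot drive cluster
membership.  Clusters are finally assigned to biological subsets (naive,
early memory, late memory, double negative) from their median marker
expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from ._rng import stream_seed
from .preprocess import PooledEventMatrix, _gmm_valley

__all__ = [
    "BatchSOM",
    "ClusterResult",
    "SubsetAssignment",
    "som_cluster",
    "embed_2d",
    "assign_subsets",
]


class BatchSOM:
    """Batch-trained self-organizing map on a rectangular grid.

    Ten batch epochs with a Gaussian neighborhood whose radius decays
    linearly from half the larger grid dimension to one; codebook
    initialized from a seeded sample of the data.  Deterministic given
    (data, seed).
    """

    def __init__(
        self,
        grid: tuple[int, int] = (10, 10),
        n_epochs: int = 10,
        seed: int = 0,
    ) -> None:
        self.grid = grid
        self.n_epochs = n_epochs
        self.seed = seed
        self.codebook: np.ndarray | None = None
        rows, cols = grid
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        pos = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        # squared grid distances between nodes
        self._grid_d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)

    @property
    def n_nodes(self) -> int:
        return self.grid[0] * self.grid[1]

    def fit(self, X: np.ndarray) -> "BatchSOM":
        X = np.asarray(X, dtype=float)
        n, _ = X.shape
        if n < self.n_nodes:
            raise ValueError(
                f"{n} events < {self.n_nodes} map nodes; use a smaller grid"
            )
        rng = np.random.default_rng(self.seed)
        init_idx = rng.choice(n, size=self.n_nodes, replace=False)
        codebook = X[init_idx].copy()
        r0 = max(self.grid) / 2.0
        for epoch in range(self.n_epochs):
            frac = epoch / max(self.n_epochs - 1, 1)
            radius = r0 + (1.0 - r0) * frac  # linear decay r0 -> 1
            bmu = self._bmu(X, codebook)
            h = np.exp(-self._grid_d2 / (2.0 * radius**2))
            sums = np.zeros_like(codebook)
            np.add.at(sums, bmu, X)
            counts = np.bincount(bmu, minlength=self.n_nodes).astype(float)
            num = h @ sums
            den = (h @ counts)[:, None]
            update = den[:, 0] > 0
            codebook[update] = num[update] / den[update]
        self.codebook = codebook
        return self

    @staticmethod
    def _bmu(X: np.ndarray, codebook: np.ndarray) -> np.ndarray:
        # ||x-c||^2 = ||x||^2 - 2 x.c + ||c||^2 ; ||x||^2 constant per row
        d = X @ codebook.T
        d *= -2.0
        d += (codebook**2).sum(1)[None, :]
        return np.argmin(d, axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.codebook is None:
            raise RuntimeError("SOM not fitted")
        return self._bmu(np.asarray(X, dtype=float), self.codebook)


@dataclass
class ClusterResult:
    """Per-event metacluster ids plus per-cluster summaries."""

    labels: np.ndarray  # per-event metacluster id (0-based)
    node_labels: np.ndarray  # per-SOM-node metacluster id
    codebook: np.ndarray
    channels: list[str]  # channels the clustering actually used
    medians: pd.DataFrame  # cluster x marker median expression (all channels)
    frequencies: pd.DataFrame  # cluster x sample event fractions
    scale_mean: np.ndarray = field(default=None, repr=False)
    scale_sd: np.ndarray = field(default=None, repr=False)

    @property
    def cluster_ids(self) -> list[int]:
        return list(self.medians.index)


def som_cluster(
    pooled: PooledEventMatrix,
    grid: tuple[int, int] = (10, 10),
    n_metaclusters: int = 10,
    seed: int = 0,
) -> ClusterResult:
    """SOM + average-linkage metaclustering of pooled events.

    Channels are the pooled matrix's clustering channels (scatter +
    backbone minus CD3), z-scored before training.  Map nodes are merged
    into ``n_metaclusters`` by average-linkage agglomeration (Euclidean
    distance between codebook vectors); each event inherits the
    metacluster of its best-matching node.
    """
    if n_metaclusters < 1 or n_metaclusters > grid[0] * grid[1]:
        raise ValueError("n_metaclusters must be in [1, grid nodes]")
    channels = pooled.clustering_channels()
    X = pooled.data[channels].to_numpy(dtype=float)
    mean = X.mean(0)
    sd = X.std(0)
    sd[sd == 0] = 1.0
    Xs = (X - mean) / sd

    som = BatchSOM(grid=grid, seed=stream_seed(seed, "som") % 2**31).fit(Xs)
    bmu = som.predict(Xs)
    if n_metaclusters == 1:
        node_labels = np.zeros(som.n_nodes, dtype=int)
    else:
        Z = linkage(som.codebook, method="average", metric="euclidean")
        node_labels = fcluster(Z, t=n_metaclusters, criterion="maxclust") - 1
    labels = node_labels[bmu]

    ids = np.unique(labels)
    medians = pd.DataFrame(
        {
            ch: [
                float(np.median(pooled.data[ch].to_numpy()[labels == k]))
                for k in ids
            ]
            for ch in pooled.channels
        },
        index=pd.Index(ids, name="cluster"),
    )
    freq = (
        pd.crosstab(labels, pooled.meta["sample_id"], normalize="columns")
        .rename_axis(index="cluster", columns="sample_id")
    )
    return ClusterResult(
        labels=labels,
        node_labels=node_labels,
        codebook=som.codebook,
        channels=channels,
        medians=medians,
        frequencies=freq,
        scale_mean=mean,
        scale_sd=sd,
    )


def embed_2d(
    pooled: PooledEventMatrix,
    perplexity: float = 30.0,
    max_iter: int = 1000,
    theta: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """t-SNE embedding of the clustering channels, for visualization only.

    No statistic in the pipeline consumes these coordinates.  Defaults
    mirror common cytometry practice (perplexity 30, 1000 iterations,
    Barnes-Hut angle 0.5).
    """
    from sklearn.manifold import TSNE

    channels = pooled.clustering_channels()
    X = pooled.data[channels].to_numpy(dtype=float)
    if len(X) < 3 * perplexity:
        raise ValueError(
            f"{len(X)} events < 3 x perplexity ({perplexity}); "
            "reduce perplexity"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=max_iter,
        angle=theta,
        init="pca",
        random_state=stream_seed(seed, "tsne") % 2**31,
    )
    return tsne.fit_transform(X)


#: Markers whose positivity drives subset assignment.
SUBSET_MARKERS = ("CD4", "CD8", "CCR7", "CD45RA", "CD27", "CD28")
#: Markers also called for expansion phenotype fingerprints.
FINGERPRINT_MARKERS = ("TIGIT", "PD-1", "CD45RA")


@dataclass
class SubsetAssignment:
    """Per-cluster subset labels and the marker calls behind them.

    Subset rules on cluster medians: naive = CCR7+CD45RA+CD27+CD28+;
    early memory = CD27+CD28+ but not naive; late memory = CD27- and/or
    CD28-.  CD4+ clusters (including CD4+CD8dim) are CD4 lineage; clusters
    negative for both coreceptors get the double-negative labels.
    """

    labels: dict[int, str]
    lineage: dict[int, str]  # CD4 | CD8 | DN
    positivity: pd.DataFrame  # cluster x marker boolean calls
    cutoffs: dict[str, float]
    flags: dict[int, str] = field(default_factory=dict)

    def clusters_with_label(self, label: str) -> list[int]:
        return [k for k, v in self.labels.items() if v == label]

    def fingerprint(self, cluster: int) -> tuple[str, ...]:
        """TIGIT/PD-1/CD45RA positivity signature of a cluster."""
        row = self.positivity.loc[cluster]
        return tuple(
            f"{m}{'+' if bool(row[m]) else '-'}" for m in FINGERPRINT_MARKERS
        )


def _auto_cutoffs(medians: pd.DataFrame, markers) -> dict[str, float]:
    """Positivity threshold per marker from cluster medians.

    Valley of a two-component Gaussian mixture when there are enough
    clusters to fit one; midpoint of the median range otherwise.
    """
    cuts: dict[str, float] = {}
    for m in markers:
        x = medians[m].to_numpy(dtype=float)
        if len(np.unique(x)) >= 4:
            cuts[m] = _gmm_valley(x)
        else:
            cuts[m] = float((x.min() + x.max()) / 2.0)
    return cuts


def assign_subsets(
    clusters: ClusterResult,
    cutoffs: dict[str, float] | None = None,
) -> SubsetAssignment:
    """Label every cluster with its biological subset.

    ``cutoffs`` maps marker -> positivity threshold on the post-transform
    scale; missing markers are auto-thresholded from the cluster medians.
    Every cluster receives a label; clusters positive for both CD4 and
    CD8 are assigned to the CD4 lineage and flagged.
    """
    markers = set(SUBSET_MARKERS) | set(FINGERPRINT_MARKERS)
    markers = [m for m in markers if m in clusters.medians.columns]
    cuts = dict(cutoffs or {})
    auto = _auto_cutoffs(
        clusters.medians, [m for m in markers if m not in cuts]
    )
    cuts.update(auto)

    pos = pd.DataFrame(
        {m: clusters.medians[m] > cuts[m] for m in markers},
        index=clusters.medians.index,
    )
    labels: dict[int, str] = {}
    lineage: dict[int, str] = {}
    flags: dict[int, str] = {}
    for k in clusters.cluster_ids:
        r = pos.loc[k]
        if r["CD4"]:
            lin = "CD4"
            if r["CD8"]:
                flags[k] = "CD4+CD8dim treated as CD4 lineage"
        elif r["CD8"]:
            lin = "CD8"
        else:
            lin = "DN"
        naive_like = r["CCR7"] and r["CD45RA"] and r["CD27"] and r["CD28"]
        if lin == "DN":
            labels[k] = (
                "double_negative_naive" if naive_like else "double_negative_memory"
            )
        elif naive_like:
            labels[k] = "naive"
        elif r["CD27"] and r["CD28"]:
            labels[k] = "early_memory"
        else:
            labels[k] = "late_memory"
        lineage[k] = lin
    return SubsetAssignment(
        labels=labels, lineage=lineage, positivity=pos, cutoffs=cuts, flags=flags
    )
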