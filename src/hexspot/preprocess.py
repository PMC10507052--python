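"""Normalization, cluster-wise differential expression, and the spot
neighbor graph.

Normalization is log-CP10K by default: ``log(1 + 1e4 * count / spot_total)``.
Spot statistics downstream (rank-based tests, correlations, running sums)
need a monotone variance-stabilized matrix, which this provides without any
model fitting; a median-of-ratios alternative is available.

Differential expression follows the one-vs-rest convention of marker
finding in single-cell toolkits: a Wilcoxon rank-sum test per gene per
cluster, a natural-log fold-change of ``(mean(expm1(x)) + 1)`` ratios so the
customary ``logFC > 0.25`` threshold applies, and Benjamini-Hochberg
adjustment across genes within each cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as sps
from scipy.spatial import cKDTree

from .containers import SpotLattice, SpotMatrix
from .errors import InvalidArgumentError
from .stats_core import adjust_pvalues

__all__ = ["NeighborGraph", "normalize", "find_cluster_degs", "build_neighbor_graph"]

log = logging.getLogger(__name__)


@dataclass
class NeighborGraph:
    """Symmetric adjacency of spots on the hexagonal lattice (degree <= 6)."""

    adjacency: dict = field(default_factory=dict)  # spot id -> list of spot ids

    def __post_init__(self):
        for spot, nbrs in self.adjacency.items():
            if spot in nbrs:
                raise InvalidArgumentError(f"self-edge at spot {spot!r}")
            if len(nbrs) > 6:
                raise InvalidArgumentError(f"spot {spot!r} has degree {len(nbrs)} > 6")
            for n in nbrs:
                if spot not in self.adjacency.get(n, ()):
                    raise InvalidArgumentError(f"asymmetric edge {spot!r} -> {n!r}")

    def neighbors(self, spot) -> list:
        return list(self.adjacency.get(spot, ()))

    def degree(self, spot) -> int:
        return len(self.adjacency.get(spot, ()))

    @property
    def spots(self) -> list:
        return list(self.adjacency)


def normalize(sm: SpotMatrix, method: str = "log_cp10k") -> pd.DataFrame:
    """Normalize raw counts to a genes x spots float DataFrame.

    ``log_cp10k``: natural log of 1 + counts-per-10k.  ``median_ratio``:
    DESeq-style size factors (median of ratios to the geometric-mean
    reference over genes expressed everywhere), then log1p.  Spots with zero
    total counts are excluded with a warning.
    """
    totals = sm.spot_totals()
    keep = totals > 0
    if not keep.any():
        raise InvalidArgumentError("all spots have zero total counts")
    if not keep.all():
        log.warning("excluding %d spots with zero total counts", (~keep).sum())
    counts = np.asarray(sm.counts[:, keep].todense(), dtype=float)
    spots = sm.spots[keep]

    if method == "log_cp10k":
        out = np.log1p(1e4 * counts / totals[keep])
    elif method == "median_ratio":
        logc = np.log(counts, where=counts > 0, out=np.full_like(counts, np.nan))
        ref = np.nanmean(np.where(counts > 0, logc, np.nan), axis=1)
        expressed = np.all(counts > 0, axis=1) & np.isfinite(ref)
        if not expressed.any():
            raise InvalidArgumentError(
                "median_ratio needs at least one gene expressed in every spot")
        size = np.exp(np.median(logc[expressed] - ref[expressed, None], axis=0))
        out = np.log1p(counts / size)
    else:
        raise InvalidArgumentError(f"unknown normalization method {method!r}")
    return pd.DataFrame(out, index=sm.genes, columns=spots)


def find_cluster_degs(norm: pd.DataFrame, labels: pd.Series,
                      min_logfc: float = 0.25, max_padj: float = 0.05) -> pd.DataFrame:
    """One-vs-rest Wilcoxon differential expression per cluster.

    Parameters
    ----------
    norm : genes x spots normalized matrix (log scale).
    labels : cluster label per spot (index must cover the matrix columns).
    min_logfc, max_padj : significance rule — a row is flagged ``significant``
        when ``logFC > min_logfc`` and ``p_adj < max_padj``.

    Returns the full table (cluster, gene, logfc, p, p_adj, pct_expressed,
    significant) for every tested gene, ordered by cluster then ascending p.
    """
    labels = labels.reindex(norm.columns)
    if labels.isna().any():
        raise InvalidArgumentError("cluster labels must cover every spot")
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise InvalidArgumentError("differential expression requires >= 2 clusters")
    sizes = labels.value_counts()
    small = sizes[sizes < 3]
    if not small.empty:
        raise InvalidArgumentError(
            f"cluster(s) with fewer than 3 spots: {sorted(small.index)}")

    x = norm.to_numpy()
    expm1 = np.expm1(x)
    frames = []
    for cl in clusters:
        mask = (labels == cl).to_numpy()
        inside, outside = x[:, mask], x[:, ~mask]
        mean_in = expm1[:, mask].mean(axis=1)
        mean_out = expm1[:, ~mask].mean(axis=1)
        logfc = np.log((mean_in + 1.0) / (mean_out + 1.0))
        pct = (inside > 0).mean(axis=1)
        pvals = _rowwise_ranksum_p(inside, outside)
        padj = adjust_pvalues(pvals, method="bh").values
        frames.append(pd.DataFrame({
            "cluster": cl, "gene": norm.index, "logfc": logfc, "p": pvals,
            "p_adj": padj, "pct_expressed": pct,
            "significant": (logfc > min_logfc) & (padj < max_padj),
        }))
    table = pd.concat(frames, ignore_index=True)
    return (table.sort_values(["cluster", "p", "gene"], kind="stable")
            .reset_index(drop=True))


def _rowwise_ranksum_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum (normal approximation, tie-corrected),
    vectorized over rows.  Matches ``scipy.stats.ranksums`` up to the tie
    correction scipy omits."""
    n1, n2 = a.shape[1], b.shape[1]
    n = n1 + n2
    combined = np.concatenate([a, b], axis=1)
    ranks = sps.rankdata(combined, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    expected = n1 * (n + 1) / 2.0
    # tie correction per row
    sorted_rows = np.sort(combined, axis=1)
    ties = np.diff(sorted_rows, axis=1) == 0
    tie_term = np.zeros(a.shape[0])
    for i in range(a.shape[0]):
        if ties[i].any():
            _, counts = np.unique(sorted_rows[i], return_counts=True)
            tie_term[i] = np.sum(counts ** 3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    z = np.zeros(a.shape[0])
    ok = var > 0
    z[ok] = (r1[ok] - expected) / np.sqrt(var[ok])
    p = 2.0 * sps.norm.sf(np.abs(z))
    p[~ok] = 1.0  # constant rows: no evidence either way
    return np.clip(p, 0.0, 1.0)


def build_neighbor_graph(lattice: SpotLattice, tolerance: float = 1e-3) -> NeighborGraph:
    """Connect spots whose center distance is within ``tolerance`` (relative)
    of the lattice pitch; interior spots of a hexagonal lattice get degree 6."""
    coords = lattice.coords()
    if len(coords) != len(np.unique(coords, axis=0)):
        raise InvalidArgumentError("duplicate spot coordinates")
    ids = list(lattice.spot_ids)
    adjacency: dict = {s: [] for s in ids}
    if len(ids) > 1:
        tree = cKDTree(coords)
        pairs = tree.query_pairs(lattice.pitch_um * (1.0 + tolerance))
        lo = lattice.pitch_um * (1.0 - tolerance)
        for i, j in pairs:
            if np.linalg.norm(coords[i] - coords[j]) >= lo:
                adjacency[ids[i]].append(ids[j])
                adjacency[ids[j]].append(ids[i])
    return NeighborGraph(adjacency)
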