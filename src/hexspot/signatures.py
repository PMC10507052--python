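"""Per-spot gene-set scoring and pathway networks.

ssGSEA dialect
--------------
For one spot, genes are ranked by expression (descending; midranks for
ties).  Walking down the ranking, the in-set running sum increments by
``|rank|^alpha`` (normalized over the set) when the gene belongs to the
set, and the out-set sum increments by ``1/(N - n_set)`` otherwise.  The
enrichment score is the *integrated difference* of the two running sums —
the sum over all positions of (in-set CDF minus out-set CDF) — with weight
exponent ``alpha = 0.25`` by default.  Scores can optionally be min-max
rescaled across spots.  Being rank-based, the score is invariant to any
strictly monotone transform of a spot's expression vector.

Differentiation proxy
---------------------
Per-spot transcriptional diversity — the number of distinct genes with at
least one count — serves as a differentiation proxy (transcriptional
diversity falls as cells differentiate; a higher score reads as *less*
differentiated).  This is a deliberately simple stand-in for trajectory
methods, tagged ``diversity`` in its outputs, optionally neighbor-smoothed
on the lattice.  Genes tracking the proxy are ranked by Pearson
correlation against it.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import GeneSetCollection, SpotMatrix
from .errors import InvalidArgumentError
from .preprocess import NeighborGraph
from .celltypes import compare_across_subtypes

__all__ = [
    "ssgsea_scores",
    "score_subtype_comparison",
    "diversity_score",
    "differentiation_correlated_genes",
    "pathway_jaccard_network",
]

log = logging.getLogger(__name__)


def ssgsea_scores(norm: pd.DataFrame, sets: GeneSetCollection,
                  alpha: float = 0.25, min_set_size: int = 2,
                  rescale: bool = False) -> pd.DataFrame:
    """Single-sample GSEA score for every (gene set, spot).

    ``norm`` is genes x spots; sets smaller than ``min_set_size`` after
    intersecting with the matrix genes are skipped with a warning.  Returns
    a gene set x spot DataFrame (``attrs["normalization"]`` records whether
    min-max rescaling across spots was applied).
    """
    if not sets:
        raise InvalidArgumentError("empty gene-set collection")
    genes = norm.index
    usable: dict[str, np.ndarray] = {}
    for name, members in sets.items():
        idx = genes.get_indexer([g for g in members if g in genes])
        if len(idx) < min_set_size:
            log.warning("gene set %s skipped: %d member(s) in matrix (< %d)",
                        name, len(idx), min_set_size)
            continue
        if len(idx) >= len(genes):
            log.warning("gene set %s skipped: covers the whole gene universe", name)
            continue
        usable[name] = np.asarray(idx)
    if not usable:
        raise InvalidArgumentError("no gene set large enough to score")

    n_genes = len(genes)
    x = norm.to_numpy(dtype=float)
    ranks = sps.rankdata(x, axis=0)  # midranks; highest expression -> rank N
    out = pd.DataFrame(index=list(usable), columns=norm.columns, dtype=float)
    for j in range(x.shape[1]):
        r = ranks[:, j]
        order = np.argsort(-r, kind="stable")  # descending rank
        r_sorted = np.abs(r[order]) ** alpha
        for name, idx in usable.items():
            in_set = np.zeros(n_genes, dtype=bool)
            in_set[idx] = True
            in_sorted = in_set[order]
            n_in = in_sorted.sum()
            step_in = np.where(in_sorted, r_sorted, 0.0)
            denom = step_in.sum()
            cdf_in = np.cumsum(step_in) / denom
            cdf_out = np.cumsum(~in_sorted) / (n_genes - n_in)
            out.iloc[out.index.get_loc(name), j] = float(np.sum(cdf_in - cdf_out))
    if rescale:
        rng_ = out.to_numpy().max() - out.to_numpy().min()
        if rng_ > 0:
            out = (out - out.to_numpy().min()) / rng_
    out.attrs["normalization"] = "minmax" if rescale else "none"
    out.attrs["alpha"] = alpha
    return out


def score_subtype_comparison(scores: pd.DataFrame, subtype: pd.Series,
                             dunn_method: str = "bonferroni") -> pd.DataFrame:
    """Kruskal-Wallis (+ Dunn) of each gene set's per-spot scores across
    histologic subtypes.  Returns one row per gene set with H and p; the
    Dunn tables are collected in ``attrs["dunn"]``."""
    rows, dunn_tables = [], {}
    for name in scores.index:
        res = compare_across_subtypes(scores.loc[name], subtype,
                                      dunn_method=dunn_method)
        rows.append({"gene_set": name, "H": res["H"], "p": res["p"]})
        dunn_tables[name] = res["dunn"]
    table = pd.DataFrame(rows).set_index("gene_set")
    table.attrs["dunn"] = dunn_tables
    return table


def diversity_score(sm: SpotMatrix, graph: NeighborGraph | None = None) -> pd.Series:
    """Transcriptional diversity per spot: number of genes with count > 0.

    Higher means less differentiated.  With ``graph``, the raw gene counts
    are averaged over {self} + neighbors on the lattice.  Sequencing depth
    changes that add no new genes leave the unsmoothed score unchanged.
    """
    raw = pd.Series(np.asarray((sm.counts > 0).sum(axis=0)).ravel(),
                    index=sm.spots, dtype=float)
    if graph is not None:
        smoothed = raw.copy()
        for spot in raw.index:
            members = [spot] + [n for n in graph.neighbors(spot) if n in raw.index]
            smoothed[spot] = raw[members].mean()
        smoothed.attrs["method"] = "diversity_smoothed"
        return smoothed
    raw.attrs["method"] = "diversity"
    return raw


def differentiation_correlated_genes(norm: pd.DataFrame,
                                     scores: pd.Series) -> pd.DataFrame:
    """Rank genes by Pearson correlation with the differentiation proxy.

    Returns the full table sorted by descending coefficient (head = genes
    tracking low differentiation, tail = genes tracking high); zero-variance
    genes are kept but marked untestable.
    """
    scores = scores.reindex(norm.columns)
    if scores.isna().any():
        raise InvalidArgumentError("scores must cover every spot")
    if norm.shape[1] < 3:
        raise InvalidArgumentError("correlation requires >= 3 spots")
    s = scores.to_numpy(dtype=float)
    if np.ptp(s) == 0:
        raise InvalidArgumentError("differentiation score is constant")
    x = norm.to_numpy(dtype=float)
    sd = x.std(axis=1)
    testable = sd > 0
    xc = x - x.mean(axis=1, keepdims=True)
    sc = s - s.mean()
    r = np.full(x.shape[0], np.nan)
    r[testable] = (xc[testable] @ sc) / (
        np.sqrt((xc[testable] ** 2).sum(axis=1)) * np.sqrt((sc ** 2).sum()))
    n = x.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1 - r ** 2, 1e-300, None))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    table = pd.DataFrame({"gene": norm.index, "coefficient": r, "p": p,
                          "testable": testable})
    return (table.sort_values("coefficient", ascending=False, kind="stable")
            .reset_index(drop=True))


def pathway_jaccard_network(sets: GeneSetCollection, min_jaccard: float = 0.0,
                            node_tags: dict | None = None) -> nx.Graph:
    """Build the pathway similarity network.

    Nodes are gene-set names (optionally tagged, e.g. with the associated
    histologic subtype); an edge joins every pair whose Jaccard index —
    intersection size over union size — exceeds ``min_jaccard``.
    """
    names = list(sets)
    if len(names) < 2:
        raise InvalidArgumentError("network requires >= 2 gene sets")
    g = nx.Graph()
    for name in names:
        g.add_node(name, subtype=(node_tags or {}).get(name, ""))
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter = len(sets[a] & sets[b])
            if inter == 0:
                continue
            j = inter / len(sets[a] | sets[b])
            if j > min_jaccard:
                g.add_edge(a, b, weight=j)
    return g
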