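"""Cluster-level cell-type analysis.

The centerpiece is multimodal intersection analysis (MIA): for each spatial
cluster and candidate cell type, the overlap between the cluster's
differentially expressed genes and the cell type's marker genes is scored
with the cumulative hypergeometric distribution over the universe of genes
tested for differential expression.  Both enrichment (upper tail) and
depletion (lower tail) p-values are reported.

Also here: a marker-score proxy for per-spot cell-type composition (for
when an externally produced anchor-transfer proportion table is not
supplied), cluster-level composition averaging, the hamming distance
between cluster composition profiles, and Kruskal-Wallis/Dunn comparisons
of per-cluster values across histologic subtypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidArgumentError
from .stats_core import (GroupedSamples, dunn_posthoc, hypergeom_lower_tail,
                         hypergeom_upper_tail, kruskal_wallis)

__all__ = [
    "CellTypeSignature",
    "mia_enrichment",
    "marker_score_composition",
    "cluster_composition",
    "composition_hamming",
    "compare_across_subtypes",
]

log = logging.getLogger(__name__)


@dataclass
class CellTypeSignature:
    """Marker gene sets per cell type (``name -> set of genes``)."""

    sets: dict
    provenance: str = "user"

    def __post_init__(self):
        cleaned = {}
        for name, genes in self.sets.items():
            genes = frozenset(genes)
            if not genes:
                raise InvalidArgumentError(f"cell type {name!r} has no markers")
            cleaned[str(name)] = genes
        self.sets = cleaned

    def intersect(self, universe) -> "CellTypeSignature":
        """Restrict markers to the analysis universe, warning about losses."""
        universe = frozenset(universe)
        kept = {}
        for name, genes in self.sets.items():
            inter = genes & universe
            if len(inter) < len(genes):
                log.warning("cell type %s: %d/%d markers absent from universe",
                            name, len(genes) - len(inter), len(genes))
            if inter:
                kept[name] = inter
        if not kept:
            raise InvalidArgumentError("no marker of any cell type present in universe")
        return CellTypeSignature(kept, self.provenance)


def mia_enrichment(deg_table: pd.DataFrame, signature: CellTypeSignature,
                   universe) -> pd.DataFrame:
    """Hypergeometric enrichment of DEG / marker-set overlaps (MIA).

    ``deg_table`` is the output of :func:`hexspot.preprocess.find_cluster_degs`;
    a cluster's DEG set is its ``significant`` genes.  ``universe`` is the
    list of genes tested for differential expression.  Returns one row per
    (cluster, cell type): overlap, deg_size, marker_size, universe_size,
    p_enrich, p_deplete, neg_log10_p_enrich.
    """
    universe = frozenset(universe)
    tested = set(deg_table["gene"])
    if not tested <= universe:
        raise InvalidArgumentError("universe must contain every tested gene")
    sig = signature.intersect(universe)
    n_universe = len(universe)

    rows = []
    for cluster, sub in deg_table.groupby("cluster"):
        degs = frozenset(sub.loc[sub["significant"], "gene"])
        if not degs:
            log.warning("cluster %s has an empty DEG set; p = 1 reported", cluster)
        for ct, markers in sig.sets.items():
            overlap = len(degs & markers)
            if degs:
                p_up = hypergeom_upper_tail(overlap, len(degs), len(markers), n_universe)
                p_dn = hypergeom_lower_tail(overlap, len(degs), len(markers), n_universe)
            else:
                p_up, p_dn = 1.0, 1.0
            rows.append({
                "cluster": cluster, "cell_type": ct, "overlap": overlap,
                "deg_size": len(degs), "marker_size": len(markers),
                "universe_size": n_universe, "p_enrich": p_up, "p_deplete": p_dn,
                "neg_log10_p_enrich": -np.log10(p_up),
            })
    return pd.DataFrame(rows)


def marker_score_composition(norm: pd.DataFrame,
                             signature: CellTypeSignature) -> pd.DataFrame:
    """Per-spot composition proxy from mean marker expression.

    ``score_t(spot)`` is the mean normalized expression of type-*t* markers,
    floored at 0; proportions are scores renormalized to sum to 1 per spot
    (uniform fallback where all scores are 0).  A coarse stand-in for
    reference-based deconvolution when no external proportion table exists.
    """
    sig = signature.intersect(norm.index)
    scores = pd.DataFrame(index=norm.columns, columns=list(sig.sets), dtype=float)
    for ct, markers in sig.sets.items():
        scores[ct] = norm.loc[sorted(markers)].mean(axis=0).clip(lower=0.0)
    totals = scores.sum(axis=1)
    zero = totals == 0
    if zero.any():
        scores.loc[zero] = 1.0
        totals = scores.sum(axis=1)
    return scores.div(totals, axis=0)


def cluster_composition(spot_composition: pd.DataFrame,
                        labels: pd.Series) -> pd.DataFrame:
    """Average per-spot proportions within each cluster (rows re-sum to 1)."""
    labels = labels.reindex(spot_composition.index)
    if labels.isna().any():
        raise InvalidArgumentError("cluster labels must cover every spot")
    out = spot_composition.groupby(labels, observed=True).mean()
    if (out.isna().any(axis=1)).any():
        raise InvalidArgumentError("empty cluster in composition averaging")
    return out.div(out.sum(axis=1), axis=0)


def composition_hamming(cluster_composition_df: pd.DataFrame,
                        presence_threshold: float = 0.01) -> pd.DataFrame:
    """Hamming distance between cluster composition profiles.

    Each cluster's profile is binarized to presence/absence at
    ``presence_threshold`` mean proportion; the distance between two
    clusters is the fraction of cell types whose presence bit differs.
    Symmetric, zero diagonal; a metric on the binarized vectors.
    """
    if not 0.0 < presence_threshold < 1.0:
        raise ConfigurationError("presence threshold must lie in (0, 1)")
    if len(cluster_composition_df) < 2:
        raise InvalidArgumentError("hamming distance requires >= 2 clusters")
    bits = (cluster_composition_df >= presence_threshold).to_numpy()
    n_types = bits.shape[1]
    d = (bits[:, None, :] != bits[None, :, :]).sum(axis=2) / n_types
    return pd.DataFrame(d, index=cluster_composition_df.index,
                        columns=cluster_composition_df.index)


def compare_across_subtypes(values: pd.Series, subtype: pd.Series,
                            dunn_method: str = "bonferroni") -> dict:
    """Kruskal-Wallis omnibus (+ Dunn post hoc for >= 3 groups) of per-unit
    values grouped by histologic subtype.

    ``values`` and ``subtype`` share an index (one entry per cluster, spot
    or slide).  Returns ``{"H", "p", "dunn"}`` where ``dunn`` is None for
    two-group designs.
    """
    subtype = subtype.reindex(values.index)
    if subtype.isna().any():
        raise InvalidArgumentError("every value needs a subtype label")
    gs = GroupedSamples(values.to_numpy(dtype=float), subtype.to_numpy())
    h, p = kruskal_wallis(gs)
    dunn = dunn_posthoc(gs, method=dunn_method) if subtype.nunique() >= 3 else None
    return {"H": h, "p": p, "dunn": dunn}
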