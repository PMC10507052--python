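"""Spatial correlation statistics over the spot lattice.

Two analyses share one machinery:

* **cell-type co-occurrence** — Pearson correlation of per-spot cell-type
  proportions across all spots, for every unordered type pair, with Holm
  adjustment across the whole family and the significance rule
  ``coefficient >= 0.3 and adjusted p < 0.05`` (both configurable);
* **gene-gene spatial correlation** — each spot's normalized expression is
  first averaged with its (up to six) hexagonal lattice neighbors, then the
  requested gene pairs are correlated the same way.  Smoothing borrows
  strength from the local neighborhood and suppresses spot-level noise.

Boundary spots average over however many neighbors they have; the Holm
family is exactly the tested pair list, recorded in the output.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, ZeroVarianceError
from .preprocess import NeighborGraph
from .stats_core import adjust_pvalues, correlation

__all__ = ["cooccurrence", "neighbor_smooth", "gene_pair_correlation",
           "correlation_table"]

log = logging.getLogger(__name__)


def correlation_table(named_vectors: dict, pairs: list, kind: str = "pearson",
                      r_min: float = 0.3, alpha: float = 0.05) -> pd.DataFrame:
    """Correlate named vector pairs; Holm-adjust jointly across the family.

    ``named_vectors`` maps a name to a 1-D array; ``pairs`` lists unordered
    ``(a, b)`` name pairs.  Pairs touching a zero-variance vector are kept
    in the table but marked untestable.  Significance flag:
    ``coefficient >= r_min`` and Holm-adjusted p < ``alpha``.
    """
    rows = []
    for a, b in pairs:
        try:
            r, p = correlation(named_vectors[a], named_vectors[b], kind=kind)
            rows.append({"a": a, "b": b, "coefficient": r, "p_raw": p,
                         "tested": True})
        except ZeroVarianceError:
            log.warning("pair (%s, %s) untestable: zero-variance input", a, b)
            rows.append({"a": a, "b": b, "coefficient": np.nan, "p_raw": np.nan,
                         "tested": False})
    table = pd.DataFrame(rows)
    table["p_adj"] = np.nan
    tested = table["tested"]
    if tested.any():
        adj = adjust_pvalues(table.loc[tested, "p_raw"].to_numpy(), method="holm")
        table.loc[tested, "p_adj"] = adj.values
    table["significant"] = (tested & (table["coefficient"] >= r_min)
                            & (table["p_adj"] < alpha))
    table.attrs["family"] = [(a, b) for a, b in pairs]
    table.attrs["kind"] = kind
    table.attrs["r_min"] = r_min
    table.attrs["alpha"] = alpha
    return table


def cooccurrence(spot_composition: pd.DataFrame, r_min: float = 0.3,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Cell-type co-occurrence across spots (Pearson + Holm).

    ``spot_composition`` is spots x cell types.  All T(T-1)/2 unordered type
    pairs are tested jointly.
    """
    if spot_composition.shape[0] < 3:
        raise InvalidArgumentError("co-occurrence requires >= 3 spots")
    types = list(spot_composition.columns)
    if len(types) < 2:
        raise InvalidArgumentError("co-occurrence requires >= 2 cell types")
    vectors = {t: spot_composition[t].to_numpy(dtype=float) for t in types}
    pairs = [(types[i], types[j]) for i in range(len(types))
             for j in range(i + 1, len(types))]
    return correlation_table(vectors, pairs, kind="pearson",
                             r_min=r_min, alpha=alpha)


def neighbor_smooth(norm: pd.DataFrame, graph: NeighborGraph) -> pd.DataFrame:
    """Average each spot with its lattice neighbors (self + up to 6).

    Spots absent from the graph are treated as isolated (their own value),
    logged once.  Shape and labels are preserved.
    """
    col_pos = {s: i for i, s in enumerate(norm.columns)}
    x = norm.to_numpy(dtype=float)
    out = np.empty_like(x)
    missing = [s for s in norm.columns if s not in graph.adjacency]
    if missing:
        log.warning("%d spots absent from neighbor graph; treated as isolated",
                    len(missing))
    for j, spot in enumerate(norm.columns):
        nbrs = [col_pos[n] for n in graph.neighbors(spot) if n in col_pos]
        members = [j] + nbrs
        out[:, j] = x[:, members].mean(axis=1)
    return pd.DataFrame(out, index=norm.index, columns=norm.columns)


def gene_pair_correlation(smoothed: pd.DataFrame, pairs: list,
                          r_min: float = 0.3, alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of neighbor-smoothed expression for selected
    gene pairs, Holm-adjusted across the requested list."""
    if smoothed.shape[1] < 3:
        raise InvalidArgumentError("gene-pair correlation requires >= 3 spots")
    for a, b in pairs:
        for g in (a, b):
            if g not in smoothed.index:
                raise InvalidArgumentError(f"unknown gene {g!r}")
    vectors = {g: smoothed.loc[g].to_numpy(dtype=float)
               for g in {g for pair in pairs for g in pair}}
    return correlation_table(vectors, list(pairs), kind="pearson",
                             r_min=r_min, alpha=alpha)
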