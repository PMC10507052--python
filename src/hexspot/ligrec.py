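"""Intra-cluster ligand-receptor interaction testing.

For each (ligand-receptor pair, spatial cluster), the observed statistic is
the mean of the ligand's and receptor's average normalized expression over
the cluster's spots (a heteromeric partner's expression is the minimum over
its subunits).  A pair is tested in a cluster only when *both* partners are
expressed (normalized value > 0) in at least ``expr_threshold`` (default
0.4) of the cluster's spots.

The null is built by randomly permuting the full cluster-label vector: each
of ``n_perm`` (default 1000) permutations shuffles the labels once and all
(pair, cluster) statistics are recomputed from that single shuffle, which
preserves the cross-pair correlation structure of the null.  The p-value is
the proportion of null means at least as large as the observed mean
("exceeded" read inclusively, so a fully degenerate null — every permuted
mean equal to the observed one — yields p = 1 rather than 0).  Its
granularity is 1/n_perm; the minimum attainable value is 0, rendered
"<1/n_perm" in summaries.  Results are bit-reproducible given the seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import LRDatabase
from .errors import ConfigurationError, InvalidArgumentError

__all__ = ["intra_cluster_lr_test", "lr_summary"]


def intra_cluster_lr_test(norm: pd.DataFrame, labels: pd.Series, db: LRDatabase,
                          expr_threshold: float = 0.4, n_perm: int = 1000,
                          seed: int = 0) -> pd.DataFrame:
    """Permutation test of joint ligand-receptor expression within clusters.

    Parameters
    ----------
    norm : genes x spots normalized expression.
    labels : cluster label per spot.
    db : ligand-receptor pair repository.
    expr_threshold : minimum fraction of cluster spots expressing each partner.
    n_perm, seed : permutation count and RNG seed.

    Returns one row per (pair, cluster) with expressed fractions, partner
    means, the observed statistic, the permutation p (NaN when untested)
    and a reason code for untested rows.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    if not 0.0 <= expr_threshold <= 1.0:
        raise ConfigurationError("expr_threshold must lie in [0, 1]")
    labels = labels.reindex(norm.columns)
    if labels.isna().any():
        raise InvalidArgumentError("cluster labels must cover every spot")
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise InvalidArgumentError("LR testing requires >= 2 clusters")

    genes_present = set(norm.index)
    label_arr = labels.to_numpy()
    cluster_masks = {c: label_arr == c for c in clusters}
    cluster_sizes = {c: int(m.sum()) for c, m in cluster_masks.items()}

    rows = []
    tested_keys = []  # (pair_id, cluster) in row order for the permutation pass
    needed_genes: set = set()
    for pid, rec in db.pairs.iterrows():
        lig, recp = rec["ligand_genes"], rec["receptor_genes"]
        missing = [g for g in (*lig, *recp) if g not in genes_present]
        for c in clusters:
            row = {"pair_id": pid, "cluster": c, "lig_frac": np.nan,
                   "rec_frac": np.nan, "lig_mean": np.nan, "rec_mean": np.nan,
                   "observed": np.nan, "p": np.nan, "tested": False, "reason": ""}
            if missing:
                row["reason"] = "missing_gene"
                rows.append(row)
                continue
            if cluster_sizes[c] < 3:
                row["reason"] = "cluster_too_small"
                rows.append(row)
                continue
            sub = norm.loc[list(lig) + list(recp)].to_numpy()[:, cluster_masks[c]]
            fracs = (sub > 0).mean(axis=1)
            means = sub.mean(axis=1)
            lig_frac = float(fracs[:len(lig)].min())
            rec_frac = float(fracs[len(lig):].min())
            row["lig_frac"], row["rec_frac"] = lig_frac, rec_frac
            row["lig_mean"] = float(means[:len(lig)].min())
            row["rec_mean"] = float(means[len(lig):].min())
            if lig_frac < expr_threshold or rec_frac < expr_threshold:
                row["reason"] = "below_threshold"
                rows.append(row)
                continue
            row["observed"] = (row["lig_mean"] + row["rec_mean"]) / 2.0
            row["tested"] = True
            rows.append(row)
            tested_keys.append((pid, c))
            needed_genes.update(lig)
            needed_genes.update(recp)

    result = pd.DataFrame(rows)
    if tested_keys:
        result = _fill_permutation_p(result, norm, db, clusters, cluster_masks,
                                     needed_genes, tested_keys, n_perm, seed)
    result.attrs["n_perm"] = n_perm
    result.attrs["seed"] = seed
    result.attrs["expr_threshold"] = expr_threshold
    return result


def _fill_permutation_p(result, norm, db, clusters, cluster_masks, needed_genes,
                        tested_keys, n_perm, seed):
    rng = np.random.default_rng(seed)
    genes = sorted(needed_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    x = norm.loc[genes].to_numpy(dtype=float)  # needed genes x spots
    n_spots = x.shape[1]
    # one-hot spot -> cluster; permuting spot order == shuffling the label vector
    ind = np.zeros((n_spots, len(clusters)))
    for j, c in enumerate(clusters):
        ind[cluster_masks[c], j] = 1.0
    sizes = ind.sum(axis=0)
    cl_pos = {c: j for j, c in enumerate(clusters)}

    observed = {}
    partners = {}
    for pid, c in tested_keys:
        rec = db.pairs.loc[pid]
        partners[pid] = ([gene_pos[g] for g in rec["ligand_genes"]],
                         [gene_pos[g] for g in rec["receptor_genes"]])
        row = result[(result["pair_id"] == pid) & (result["cluster"] == c)]
        observed[(pid, c)] = float(row["observed"].iloc[0])

    exceed = {k: 0 for k in tested_keys}
    for _ in range(n_perm):
        perm = rng.permutation(n_spots)
        means = (x @ ind[perm]) / sizes  # needed genes x clusters
        for pid, c in tested_keys:
            lig_idx, rec_idx = partners[pid]
            j = cl_pos[c]
            stat = (means[lig_idx, j].min() + means[rec_idx, j].min()) / 2.0
            if stat >= observed[(pid, c)]:
                exceed[(pid, c)] += 1

    for (pid, c), count in exceed.items():
        sel = (result["pair_id"] == pid) & (result["cluster"] == c)
        result.loc[sel, "p"] = count / n_perm
    return result


def lr_summary(result: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Significant (pair, cluster) rows, sorted by p then by observed mean.

    Zero p-values (no null mean exceeded the observed one) are displayed as
    ``<1/n_perm``.  Output is dot-plot ready: one row per significant
    interaction with its expression means and significance.
    """
    n_perm = result.attrs.get("n_perm", None)
    sig = result[(result["tested"]) & (result["p"] < alpha)].copy()
    sig = sig.sort_values(["p", "observed"], ascending=[True, False],
                          kind="stable").reset_index(drop=True)
    if n_perm:
        sig["p_display"] = [f"<1/{n_perm}" if p == 0 else f"{p:g}"
                            for p in sig["p"]]
    return sig
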