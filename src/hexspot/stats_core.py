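"""Statistical primitives used by every pipeline stage.

These are thin, strictly-validated wrappers around scipy/statsmodels plus a
hand-implemented Dunn post hoc test.  Conventions used throughout:

* ties are handled with midranks and tie corrections (Kruskal-Wallis and Dunn);
* p-values are computed in log space where underflow is a risk and reported
  clipped to ``[5e-324, 1]``;
* a correlation on a constant vector raises :class:`ZeroVarianceError` rather
  than silently returning 0 or NaN, so pipelines fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InvalidArgumentError, ZeroVarianceError

__all__ = [
    "PValueVector",
    "GroupedSamples",
    "hypergeom_upper_tail",
    "hypergeom_lower_tail",
    "adjust_pvalues",
    "kruskal_wallis",
    "dunn_posthoc",
    "correlation",
]

#: smallest positive subnormal double; lower clip bound for reported p-values
P_FLOOR = 5e-324

_ADJUST_METHODS = {"bh": "fdr_bh", "holm": "holm", "bonferroni": "bonferroni"}


def _clip_p(p):
    return np.clip(p, P_FLOOR, 1.0)


@dataclass
class PValueVector:
    """A labelled vector of p-values from one family of tests."""

    values: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise InvalidArgumentError("p-value vector must be non-empty and 1-D")
        if np.any((self.values < 0) | (self.values > 1) | ~np.isfinite(self.values)):
            raise InvalidArgumentError("p-values must lie in [0, 1]")
        if not self.labels:
            self.labels = [f"test_{i}" for i in range(self.values.size)]
        if len(self.labels) != self.values.size:
            raise InvalidArgumentError("labels and values must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise InvalidArgumentError("labels must be unique")


@dataclass
class GroupedSamples:
    """Real-valued measurements with a categorical group label per value."""

    values: np.ndarray
    group: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.group = np.asarray(self.group)
        if self.values.shape != self.group.shape or self.values.ndim != 1:
            raise InvalidArgumentError("values and group must be equal-length 1-D arrays")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("values must be finite")
        labels, counts = np.unique(self.group, return_counts=True)
        if labels.size < 2:
            raise InvalidArgumentError("grouped samples require >= 2 groups")
        if np.any(counts == 0):
            raise InvalidArgumentError("every group must be non-empty")

    def split(self) -> dict:
        return {g: self.values[self.group == g] for g in np.unique(self.group)}


def hypergeom_upper_tail(overlap: int, set1_size: int, set2_size: int,
                         universe_size: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= overlap)``.

    ``X`` counts the overlap when a subset of ``set2_size`` elements is drawn
    without replacement from a universe of ``universe_size`` elements of which
    ``set1_size`` are marked.  This is the enrichment p-value used to score the
    overlap between a cluster's differentially expressed genes and a cell
    type's marker genes.

    Computed via the log survival function for numerical stability.
    """
    overlap, set1_size, set2_size, universe_size = (
        int(overlap), int(set1_size), int(set2_size), int(universe_size))
    if universe_size < 0 or set1_size < 0 or set2_size < 0:
        raise InvalidArgumentError("sizes must be non-negative")
    if set1_size > universe_size or set2_size > universe_size:
        raise InvalidArgumentError(
            f"set sizes ({set1_size}, {set2_size}) exceed universe size {universe_size}")
    if overlap < 0 or overlap > min(set1_size, set2_size):
        raise InvalidArgumentError(
            f"overlap {overlap} outside [0, min(set sizes) = {min(set1_size, set2_size)}]")
    if overlap == 0:
        return 1.0
    logp = sps.hypergeom.logsf(overlap - 1, universe_size, set1_size, set2_size)
    return float(_clip_p(np.exp(logp)))


def hypergeom_lower_tail(overlap: int, set1_size: int, set2_size: int,
                         universe_size: int) -> float:
    """Lower-tail (depletion) probability ``P(X <= overlap)``; see upper tail."""
    overlap, set1_size, set2_size, universe_size = (
        int(overlap), int(set1_size), int(set2_size), int(universe_size))
    if set1_size > universe_size or set2_size > universe_size:
        raise InvalidArgumentError("set sizes exceed universe size")
    if overlap < 0 or overlap > min(set1_size, set2_size):
        raise InvalidArgumentError("overlap outside valid range")
    logp = sps.hypergeom.logcdf(overlap, universe_size, set1_size, set2_size)
    return float(_clip_p(np.exp(logp)))


def adjust_pvalues(p, method: str = "bh", labels=None) -> PValueVector:
    """Adjust a family of p-values for multiple testing.

    Parameters
    ----------
    p : array-like or PValueVector
        Raw p-values in [0, 1].
    method : {"bh", "holm", "bonferroni"}
        Benjamini-Hochberg step-up FDR, Holm step-down FWER, or Bonferroni.

    Returns a :class:`PValueVector` of adjusted values in the input order.
    """
    if isinstance(p, PValueVector):
        labels = p.labels
        p = p.values
    pv = PValueVector(np.asarray(p, dtype=float), list(labels) if labels else [])
    if method not in _ADJUST_METHODS:
        raise ConfigurationError(
            f"unknown adjustment method {method!r}; expected one of {sorted(_ADJUST_METHODS)}")
    _, adjusted, _, _ = multipletests(pv.values, method=_ADJUST_METHODS[method])
    return PValueVector(_clip_p(adjusted), pv.labels)


def kruskal_wallis(samples: GroupedSamples) -> tuple[float, float]:
    """Kruskal-Wallis rank-sum omnibus test.

    Midrank ties with tie correction; the p-value comes from the chi-squared
    approximation with k-1 degrees of freedom.  Returns ``(H, p)``.
    """
    groups = list(samples.split().values())
    if samples.values.size < 3:
        raise InvalidArgumentError("Kruskal-Wallis requires total n >= 3")
    if np.ptp(samples.values) == 0:
        # all pooled values identical: no rank variance, H = 0 by definition
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(_clip_p(p))


def dunn_posthoc(samples: GroupedSamples, method: str = "bonferroni") -> pd.DataFrame:
    """Dunn's post hoc test for all group pairs after a Kruskal-Wallis test.

    For groups i, j with midrank means ``Rbar_i, Rbar_j`` over the pooled
    ranking of all N observations,

        z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j))

    where ``T = sum(t^3 - t) / (12 (N - 1))`` corrects for tie groups of size
    t.  Two-sided p from the standard normal, adjusted with ``method``
    (default Bonferroni).

    Returns a DataFrame with one row per unordered pair:
    ``group1, group2, z, p_raw, p_adj``.
    """
    by_group = samples.split()
    names = sorted(by_group)
    if len(names) < 2:
        raise InvalidArgumentError("Dunn post hoc requires >= 2 groups")
    n = {g: v.size for g, v in by_group.items()}
    big_n = samples.values.size
    ranks = sps.rankdata(samples.values)
    rank_mean = {g: ranks[samples.group == g].mean() for g in names}
    _, tie_counts = np.unique(samples.values, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (big_n - 1))
    base_var = big_n * (big_n + 1) / 12.0 - tie_term

    rows = []
    for a_idx in range(len(names)):
        for b_idx in range(a_idx + 1, len(names)):
            a, b = names[a_idx], names[b_idx]
            se = np.sqrt(base_var * (1.0 / n[a] + 1.0 / n[b]))
            z = 0.0 if se == 0 else (rank_mean[a] - rank_mean[b]) / se
            p_raw = float(_clip_p(2.0 * sps.norm.sf(abs(z))))
            rows.append({"group1": a, "group2": b, "z": float(z), "p_raw": p_raw})
    table = pd.DataFrame(rows)
    adj = adjust_pvalues(table["p_raw"].to_numpy(), method=method)
    table["p_adj"] = adj.values
    return table


def correlation(x, y, kind: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and p-value between two equal-length vectors.

    ``kind="pearson"`` or ``"spearman"`` (Pearson on midranks).  Raises
    :class:`ZeroVarianceError` on a constant input, where the coefficient is
    undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise InvalidArgumentError("correlation requires length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidArgumentError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined for a zero-variance input")
    if kind == "pearson":
        r, p = sps.pearsonr(x, y)
    elif kind == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ConfigurationError(f"unknown correlation kind {kind!r}")
    return float(r), float(_clip_p(p))
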