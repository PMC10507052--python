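"""Quantification of multiplex-IHC cell tables.

Cells come in as a point pattern per slide (pixel coordinates, boolean
marker columns, tumor/stroma compartment).  Phenotypes are *data*, not
code: a :class:`PhenotypeRule` names required-positive and required-negative
markers (e.g. ``CD68+CD163+CD206-``), and a cell may satisfy several rules
at once.

Quantities:

* **density** — cells per mm^2, with compartment areas converted from px^2
  via ``area_mm2 = area_px2 * (um_per_px)^2 / 1e6``;
* **tumor proximity** — per phenotype cell, the Euclidean distance to the
  nearest PanCK+ (tumor) cell in micrometers, summarized per slide by the
  median (mean by flag);
* **co-localization** — Spearman correlation of two phenotypes' densities
  across slides, Holm-adjusted across the requested pairs;
* **subtype comparison** — Kruskal-Wallis + Dunn of densities across
  histologic subtypes, one observation per slide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .containers import CellTable
from .errors import ConfigurationError, InvalidArgumentError
from .celltypes import compare_across_subtypes
from .spatialstats import correlation_table

__all__ = [
    "PhenotypeRule",
    "gate_phenotypes",
    "densities",
    "proximity_to_tumor",
    "colocalization",
    "density_subtype_comparison",
    "TUMOR_RULE",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhenotypeRule:
    """A marker gate: positive markers required true, negative required false."""

    name: str
    positive: frozenset = field(default_factory=frozenset)
    negative: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "positive", frozenset(self.positive))
        object.__setattr__(self, "negative", frozenset(self.negative))
        if self.positive & self.negative:
            raise ConfigurationError(
                f"rule {self.name!r}: markers {sorted(self.positive & self.negative)} "
                "listed both positive and negative")
        if not (self.positive or self.negative):
            raise ConfigurationError(f"rule {self.name!r} constrains no marker")

    @classmethod
    def from_string(cls, spec: str) -> "PhenotypeRule":
        """Parse ``"CD68+CD163+CD206-"`` into a rule (named after the string).

        Accepts ASCII ``-`` and the typographic minus used in figure panels.
        """
        pos, neg = [], []
        token = ""
        for ch in spec:
            if ch in "+-−–":
                if not token:
                    raise ConfigurationError(f"malformed phenotype spec {spec!r}")
                (pos if ch == "+" else neg).append(token)
                token = ""
            else:
                token += ch
        if token:
            raise ConfigurationError(
                f"phenotype spec {spec!r} ends without +/- sign")
        return cls(spec, frozenset(pos), frozenset(neg))


#: PanCK+ tumor-cell gate used by proximity analysis
TUMOR_RULE = PhenotypeRule("PanCK+", frozenset({"PanCK"}))


def gate_phenotypes(ct: CellTable, rules: list) -> pd.DataFrame:
    """Boolean membership per cell per rule (rules are not exclusive)."""
    for rule in rules:
        unknown = (rule.positive | rule.negative) - set(ct.markers)
        if unknown:
            raise ConfigurationError(
                f"rule {rule.name!r} references unknown markers {sorted(unknown)}")
    out = pd.DataFrame(index=ct.cells.index)
    for rule in rules:
        member = np.ones(len(ct.cells), dtype=bool)
        for m in rule.positive:
            member &= ct.cells[m].to_numpy()
        for m in rule.negative:
            member &= ~ct.cells[m].to_numpy()
        out[rule.name] = member
    return out


def densities(ct: CellTable, rules: list, by_compartment: bool = True) -> pd.DataFrame:
    """Cell densities (cells/mm^2) per slide, compartment and phenotype.

    With ``by_compartment=False`` only whole-slide rows (compartment
    ``"all"``) are produced; otherwise both per-compartment and whole-slide
    rows appear.
    """
    membership = gate_phenotypes(ct, rules)
    rows = []
    for slide in ct.slides:
        in_slide = ct.cells["slide"] == slide
        scopes = [("all", in_slide)]
        if by_compartment:
            scopes += [(comp, in_slide & (ct.cells["compartment"] == comp))
                       for comp in ct.compartments]
        for comp, mask in scopes:
            area = ct.area_mm2(slide, None if comp == "all" else comp)
            if area <= 0:
                raise InvalidArgumentError(
                    f"zero area for slide {slide!r} compartment {comp!r}")
            for rule in rules:
                count = int((membership.loc[mask.to_numpy(), rule.name]).sum())
                rows.append({"slide": slide,
                             "subtype": ct.slide_meta.loc[slide, "subtype"],
                             "compartment": comp, "phenotype": rule.name,
                             "count": count, "area_mm2": area,
                             "density": count / area})
    return pd.DataFrame(rows)


def proximity_to_tumor(ct: CellTable, rules: list,
                       summary: str = "median") -> pd.DataFrame:
    """Distance from each phenotype's cells to the nearest PanCK+ cell.

    Distances are Euclidean in pixel space, converted to micrometers via
    the slide's ``um_per_px``.  Slides with no PanCK+ cell are skipped with
    a warning.  Returns per (slide, phenotype): n_cells, summary distance.
    """
    if summary not in {"median", "mean"}:
        raise ConfigurationError(f"unknown proximity summary {summary!r}")
    membership = gate_phenotypes(ct, rules)
    tumor_mask = gate_phenotypes(ct, [TUMOR_RULE])[TUMOR_RULE.name]
    reducer = np.median if summary == "median" else np.mean
    rows = []
    for slide in ct.slides:
        in_slide = (ct.cells["slide"] == slide).to_numpy()
        tumor_xy = ct.cells.loc[in_slide & tumor_mask, ["x_px", "y_px"]].to_numpy()
        if len(tumor_xy) == 0:
            log.warning("slide %s skipped: no PanCK+ cell", slide)
            continue
        tree = cKDTree(tumor_xy)
        um = float(ct.slide_meta.loc[slide, "um_per_px"])
        for rule in rules:
            xy = ct.cells.loc[in_slide & membership[rule.name],
                              ["x_px", "y_px"]].to_numpy()
            if len(xy) == 0:
                rows.append({"slide": slide, "phenotype": rule.name,
                             "n_cells": 0, f"{summary}_distance_um": np.nan})
                continue
            d, _ = tree.query(xy)
            rows.append({"slide": slide, "phenotype": rule.name,
                         "n_cells": len(xy),
                         f"{summary}_distance_um": float(reducer(d) * um)})
    return pd.DataFrame(rows)


def colocalization(density_table: pd.DataFrame, pairs: list,
                   compartment: str = "all", subtypes: list | None = None,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Spearman correlation of phenotype densities across slides.

    ``pairs`` lists (phenotype, phenotype) name pairs; ``subtypes`` may
    restrict the slides considered (e.g. acinar + solid only).  Holm
    adjustment across the requested pairs; slide count must be >= 3.
    """
    sub = density_table[density_table["compartment"] == compartment]
    if subtypes is not None:
        sub = sub[sub["subtype"].isin(subtypes)]
    wide = sub.pivot_table(index="slide", columns="phenotype", values="density")
    if len(wide) < 3:
        raise InvalidArgumentError("co-localization requires >= 3 slides")
    vectors = {ph: wide[ph].to_numpy(dtype=float) for ph in wide.columns}
    for a, b in pairs:
        for ph in (a, b):
            if ph not in vectors:
                raise InvalidArgumentError(f"phenotype {ph!r} absent from densities")
    # r_min is a spot co-occurrence rule; for densities significance is p-only
    return correlation_table(vectors, list(pairs), kind="spearman",
                             r_min=-1.0, alpha=alpha)


def density_subtype_comparison(density_table: pd.DataFrame, phenotype: str,
                               compartment: str = "all",
                               dunn_method: str = "bonferroni") -> dict:
    """Kruskal-Wallis + Dunn of one phenotype's density across subtypes
    (one observation per slide)."""
    sub = density_table[(density_table["phenotype"] == phenotype)
                        & (density_table["compartment"] == compartment)]
    if sub.empty:
        raise InvalidArgumentError(f"no density rows for phenotype {phenotype!r}")
    values = sub.set_index("slide")["density"]
    subtype = sub.set_index("slide")["subtype"]
    return compare_across_subtypes(values, subtype, dunn_method=dunn_method)
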