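"""Core in-memory containers shared across pipeline stages.

All containers validate their invariants at construction, so downstream code
can assume well-formed inputs.  They are deliberately light wrappers over
pandas frames and scipy sparse matrices: every one round-trips through the
plain-text formats in :mod:`hexspot.stio`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import FormatError, InvalidArgumentError

__all__ = [
    "SpotLattice",
    "SpotMatrix",
    "GeneSetCollection",
    "LRDatabase",
    "CellTable",
    "MARKER_COLUMNS",
]

#: default mIHC marker panel (boolean columns of a cell table)
MARKER_COLUMNS = ["PanCK", "CD68", "CD163", "CD206", "IRF8"]


@dataclass
class SpotLattice:
    """Spot identities with array indices and physical coordinates.

    ``table`` is indexed by spot barcode with integer columns ``array_row``,
    ``array_col`` and float columns ``x_um``, ``y_um``.  Spots pack
    hexagonally: odd array rows are offset by half a pitch in x and rows are
    spaced ``pitch_um * sqrt(3)/2`` apart, so each interior spot has six
    neighbors at exactly ``pitch_um`` center-to-center.
    """

    table: pd.DataFrame
    pitch_um: float = 100.0
    diameter_um: float = 55.0

    def __post_init__(self):
        required = {"array_row", "array_col", "x_um", "y_um"}
        missing = required - set(self.table.columns)
        if missing:
            raise InvalidArgumentError(f"lattice table missing columns {sorted(missing)}")
        if self.pitch_um <= 0 or self.diameter_um <= 0:
            raise InvalidArgumentError("pitch and diameter must be positive")
        if self.pitch_um <= self.diameter_um:
            raise InvalidArgumentError("pitch must exceed spot diameter")
        if self.table.index.has_duplicates:
            raise InvalidArgumentError("duplicate spot barcodes")
        rc = self.table[["array_row", "array_col"]]
        if rc.duplicated().any():
            raise InvalidArgumentError("duplicate (array_row, array_col) positions")

    @property
    def spot_ids(self) -> pd.Index:
        return self.table.index

    @property
    def n_spots(self) -> int:
        return len(self.table)

    def coords(self) -> np.ndarray:
        """(n_spots, 2) array of physical x/y coordinates in micrometers."""
        return self.table[["x_um", "y_um"]].to_numpy(dtype=float)


@dataclass
class SpotMatrix:
    """Gene x spot raw counts plus per-spot annotations.

    ``counts`` is a sparse non-negative integer matrix with rows aligned to
    ``genes`` and columns to ``spots``.  ``annotations`` is indexed by spot
    barcode and typically carries ``cluster``, ``subtype`` and ``sample``
    columns.
    """

    genes: pd.Index
    spots: pd.Index
    counts: sparse.csr_matrix
    annotations: pd.DataFrame = field(default=None)

    def __post_init__(self):
        self.genes = pd.Index(self.genes)
        self.spots = pd.Index(self.spots)
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.spots)):
            raise InvalidArgumentError(
                f"counts shape {self.counts.shape} != (genes={len(self.genes)}, "
                f"spots={len(self.spots)})")
        if self.genes.has_duplicates:
            raise InvalidArgumentError("gene identifiers must be unique")
        if self.spots.has_duplicates:
            raise InvalidArgumentError("spot barcodes must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise InvalidArgumentError("counts must be non-negative")
        if self.annotations is None:
            self.annotations = pd.DataFrame(index=self.spots)
        if not self.annotations.index.equals(self.spots):
            self.annotations = self.annotations.reindex(self.spots)
            if self.annotations.isna().all(axis=1).any():
                raise InvalidArgumentError("annotation rows must be 1:1 with spots")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def spot_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()


class GeneSetCollection(dict):
    """Named gene sets (``name -> frozenset`` of gene identifiers).

    Set names are unique by construction (dict keys); empty sets are
    rejected.  Descriptions ride along in :attr:`descriptions`.
    """

    def __init__(self, sets: dict, descriptions: dict | None = None):
        cleaned = {}
        for name, genes in sets.items():
            genes = frozenset(genes)
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            cleaned[str(name)] = genes
        super().__init__(cleaned)
        self.descriptions = {str(k): str(v) for k, v in (descriptions or {}).items()}

    def intersect(self, universe) -> "GeneSetCollection":
        """Restrict every set to ``universe``, dropping sets that become empty."""
        universe = frozenset(universe)
        kept = {n: g & universe for n, g in self.items() if g & universe}
        return GeneSetCollection(kept, self.descriptions)


@dataclass
class LRDatabase:
    """Ligand-receptor pair repository; heteromeric partners are gene lists."""

    pairs: pd.DataFrame  # index pair_id; columns ligand_genes, receptor_genes (tuples)

    def __post_init__(self):
        if self.pairs.index.has_duplicates:
            raise FormatError("pair ids must be unique")
        for col in ("ligand_genes", "receptor_genes"):
            if col not in self.pairs.columns:
                raise FormatError(f"LR table missing column {col!r}")
            if any(len(tuple(v)) == 0 for v in self.pairs[col]):
                raise FormatError("ligand/receptor partners must be non-empty")
            self.pairs[col] = [tuple(v) for v in self.pairs[col]]

    @classmethod
    def from_pairs(cls, pairs: dict) -> "LRDatabase":
        """Build from ``{pair_id: (ligand_genes, receptor_genes)}``; strings allowed."""
        rows = {}
        for pid, (lig, rec) in pairs.items():
            lig = (lig,) if isinstance(lig, str) else tuple(lig)
            rec = (rec,) if isinstance(rec, str) else tuple(rec)
            rows[pid] = {"ligand_genes": lig, "receptor_genes": rec}
        return cls(pd.DataFrame.from_dict(rows, orient="index"))

    def genes(self) -> frozenset:
        out = set()
        for _, row in self.pairs.iterrows():
            out.update(row["ligand_genes"])
            out.update(row["receptor_genes"])
        return frozenset(out)


@dataclass
class CellTable:
    """mIHC point pattern: phenotyped cells on one or more slides.

    ``cells`` has one row per cell with columns ``slide``, ``subtype``,
    ``compartment`` (tumor/stroma), ``x_px``, ``y_px`` and one boolean column
    per marker.  ``slide_meta`` is indexed by slide id with ``um_per_px``,
    ``subtype`` and one ``area_px2_<compartment>`` column per compartment.
    """

    cells: pd.DataFrame
    slide_meta: pd.DataFrame
    markers: list[str] = field(default_factory=lambda: list(MARKER_COLUMNS))

    def __post_init__(self):
        required = {"slide", "subtype", "compartment", "x_px", "y_px"}
        missing = required - set(self.cells.columns)
        if missing:
            raise InvalidArgumentError(f"cell table missing columns {sorted(missing)}")
        for m in self.markers:
            if m not in self.cells.columns:
                raise InvalidArgumentError(f"marker column {m!r} missing from cell table")
            self.cells[m] = self.cells[m].astype(bool)
        if (self.slide_meta["um_per_px"] <= 0).any():
            raise InvalidArgumentError("um_per_px must be positive")
        area_cols = [c for c in self.slide_meta.columns if c.startswith("area_px2_")]
        if not area_cols:
            raise InvalidArgumentError("slide metadata needs area_px2_<compartment> columns")
        if (self.slide_meta[area_cols] <= 0).any().any():
            raise InvalidArgumentError("compartment areas must be positive")
        unknown = set(self.cells["slide"]) - set(self.slide_meta.index)
        if unknown:
            raise InvalidArgumentError(f"cells reference unknown slides {sorted(unknown)}")

    @property
    def compartments(self) -> list[str]:
        return [c.removeprefix("area_px2_") for c in self.slide_meta.columns
                if c.startswith("area_px2_")]

    @property
    def slides(self) -> pd.Index:
        return self.slide_meta.index

    def area_mm2(self, slide, compartment: str | None = None) -> float:
        """Compartment (or whole-slide) area in mm^2: px^2 * (um/px)^2 / 1e6."""
        meta = self.slide_meta.loc[slide]
        scale = float(meta["um_per_px"]) ** 2 / 1e6
        if compartment is None:
            px2 = float(sum(meta[f"area_px2_{c}"] for c in self.compartments))
        else:
            px2 = float(meta[f"area_px2_{compartment}"])
        return px2 * scale
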