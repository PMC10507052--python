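"""Readers and writers for every on-disk format the pipeline touches.

Formats: MatrixMarket counts + feature/barcode TSVs, tissue-positions CSV
(Space-Ranger dialect, headered or headerless), annotation CSV, GMT gene
sets, ligand-receptor pair CSV, mIHC cell-table CSV pairs, YAML configs.
``.gz`` paths are handled transparently everywhere.  Writers emit exactly
what the corresponding reader accepts, and every reader either loads the
file completely or raises :class:`FormatError` naming the problem — rows
are never silently dropped.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .containers import (MARKER_COLUMNS, CellTable, GeneSetCollection,
                         LRDatabase, SpotLattice, SpotMatrix)
from .errors import FormatError

__all__ = [
    "read_counts", "write_counts",
    "read_spot_positions", "write_spot_positions",
    "read_annotations", "write_annotations",
    "read_gmt", "write_gmt",
    "read_lr_pairs", "write_lr_pairs",
    "read_cell_table", "write_cell_table",
    "load_yaml", "dump_yaml",
]

log = logging.getLogger(__name__)

_POSITION_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col",
                     "pixel_row", "pixel_col"]


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _read_lines(path) -> list[str]:
    with _open(path) as fh:
        return [ln.rstrip("\n") for ln in fh]


# ---------------------------------------------------------------- counts ----

def read_counts(matrix_path, features_path, barcodes_path,
                annotations: pd.DataFrame | None = None) -> SpotMatrix:
    """Load a gene x spot count matrix from MTX + feature/barcode TSVs.

    Dimensions must match the MatrixMarket header; entries must be
    non-negative integers.  Duplicate feature names are disambiguated
    deterministically with ``.1``, ``.2`` suffixes in file order.
    """
    try:
        with _open(matrix_path, "rb") as fh:
            mat = spio.mmread(fh)
    except Exception as exc:  # scipy raises assorted ValueErrors on bad files
        raise FormatError(f"{matrix_path}: not a valid MatrixMarket file: {exc}") from exc
    mat = sparse.csr_matrix(mat)
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        bad = np.flatnonzero(~np.isclose(mat.data, np.round(mat.data)))[0]
        raise FormatError(f"{matrix_path}: non-integer count at stored entry {bad + 1}")
    if mat.nnz and mat.data.min() < 0:
        raise FormatError(f"{matrix_path}: negative count entry")
    mat = mat.astype(np.int64)

    features = [ln.split("\t")[0] for ln in _read_lines(features_path) if ln]
    barcodes = [ln.split("\t")[0] for ln in _read_lines(barcodes_path) if ln]
    if len(features) != mat.shape[0]:
        raise FormatError(
            f"{features_path}: {len(features)} features but matrix header says "
            f"{mat.shape[0]} rows")
    if len(barcodes) != mat.shape[1]:
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrix header says "
            f"{mat.shape[1]} columns")
    features = _deduplicate(features)
    return SpotMatrix(genes=pd.Index(features), spots=pd.Index(barcodes),
                      counts=mat, annotations=annotations)


def _deduplicate(names: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}.{seen[name]}")
            log.warning("duplicate feature %r renamed to %r", name, out[-1])
        else:
            seen[name] = 0
            out.append(name)
    return out


def write_counts(sm: SpotMatrix, matrix_path, features_path, barcodes_path) -> None:
    with _open(matrix_path, "wb") as fh:
        spio.mmwrite(fh, sparse.coo_matrix(sm.counts), field="integer")
    with _open(features_path, "wt") as fh:
        fh.writelines(f"{g}\n" for g in sm.genes)
    with _open(barcodes_path, "wt") as fh:
        fh.writelines(f"{b}\n" for b in sm.spots)


# ------------------------------------------------------------- positions ----

def read_spot_positions(path, um_per_px: float = 1.0, pitch_um: float = 100.0,
                        diameter_um: float = 55.0, keep_filtered: bool = False
                        ) -> SpotLattice:
    """Load a tissue-positions CSV into a :class:`SpotLattice`.

    Accepts both the headered and the headerless 6-column dialect
    (barcode, in_tissue, array_row, array_col, pixel_row, pixel_col).
    Physical coordinates are ``pixel * um_per_px``; by default only
    ``in_tissue == 1`` spots are retained.
    """
    with _open(path) as fh:
        first = fh.readline()
    has_header = "barcode" in first.lower()
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] != len(_POSITION_COLUMNS):
        raise FormatError(
            f"{path}: expected {len(_POSITION_COLUMNS)} columns, found {df.shape[1]}")
    df.columns = _POSITION_COLUMNS
    if df["barcode"].isna().any():
        raise FormatError(f"{path}: missing barcode value")
    if not keep_filtered:
        df = df[df["in_tissue"].astype(int) == 1]
    table = pd.DataFrame({
        "array_row": df["array_row"].astype(int).to_numpy(),
        "array_col": df["array_col"].astype(int).to_numpy(),
        "x_um": df["pixel_col"].astype(float).to_numpy() * um_per_px,
        "y_um": df["pixel_row"].astype(float).to_numpy() * um_per_px,
    }, index=pd.Index(df["barcode"].astype(str)).rename(None))
    return SpotLattice(table, pitch_um=pitch_um, diameter_um=diameter_um)


def write_spot_positions(lattice: SpotLattice, path, um_per_px: float = 1.0,
                         header: bool = True) -> None:
    df = pd.DataFrame({
        "barcode": lattice.spot_ids,
        "in_tissue": 1,
        "array_row": lattice.table["array_row"].to_numpy(),
        "array_col": lattice.table["array_col"].to_numpy(),
        "pixel_row": lattice.table["y_um"].to_numpy() / um_per_px,
        "pixel_col": lattice.table["x_um"].to_numpy() / um_per_px,
    })
    with _open(path, "wt") as fh:
        df.to_csv(fh, index=False, header=header)


# ------------------------------------------------------------ annotations ----

def read_annotations(path) -> pd.DataFrame:
    """Per-spot (or per-cluster) annotation CSV, first column = identifier."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: annotation CSV needs an id column plus data")
    df = df.set_index(df.columns[0])
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate identifiers in annotation table")
    return df


def write_annotations(df: pd.DataFrame, path) -> None:
    with _open(path, "wt") as fh:
        df.to_csv(fh, index=True)


# ------------------------------------------------------------------- GMT ----

def read_gmt(path) -> GeneSetCollection:
    """GMT: one set per line — name, description, then tab-separated genes."""
    sets: dict = {}
    descriptions: dict = {}
    for lineno, ln in enumerate(_read_lines(path), start=1):
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has no genes")
        name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        if not genes:
            raise FormatError(f"{path}:{lineno}: empty gene list for set {name!r}")
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = genes
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with _open(path, "wt") as fh:
        for name in collection:
            desc = collection.descriptions.get(name, "")
            genes = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


# -------------------------------------------------------------- LR pairs ----

def read_lr_pairs(path) -> LRDatabase:
    """CSV schema: pair_id, ligand_genes (pipe-separated), receptor_genes."""
    df = pd.read_csv(path)
    required = {"pair_id", "ligand_genes", "receptor_genes"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df["pair_id"].duplicated().any():
        dup = df.loc[df["pair_id"].duplicated(), "pair_id"].iloc[0]
        raise FormatError(f"{path}: duplicate pair id {dup!r}")
    pairs = {}
    for _, row in df.iterrows():
        lig_raw, rec_raw = row["ligand_genes"], row["receptor_genes"]
        lig = tuple(g for g in str(lig_raw).split("|") if g) if pd.notna(lig_raw) else ()
        rec = tuple(g for g in str(rec_raw).split("|") if g) if pd.notna(rec_raw) else ()
        if not lig or not rec:
            raise FormatError(f"{path}: empty partner for pair {row['pair_id']!r}")
        pairs[row["pair_id"]] = (lig, rec)
    return LRDatabase.from_pairs(pairs)


def write_lr_pairs(db: LRDatabase, path) -> None:
    df = pd.DataFrame({
        "pair_id": db.pairs.index,
        "ligand_genes": ["|".join(v) for v in db.pairs["ligand_genes"]],
        "receptor_genes": ["|".join(v) for v in db.pairs["receptor_genes"]],
    })
    with _open(path, "wt") as fh:
        df.to_csv(fh, index=False)


# ------------------------------------------------------------ cell tables ----

def read_cell_table(cells_path, slide_meta_path,
                    markers: list[str] | None = None) -> CellTable:
    """mIHC cell table: per-cell CSV plus per-slide metadata CSV."""
    markers = list(markers) if markers is not None else list(MARKER_COLUMNS)
    cells = pd.read_csv(cells_path)
    required = {"slide", "subtype", "compartment", "x_px", "y_px", *markers}
    missing = required - set(cells.columns)
    if missing:
        raise FormatError(f"{cells_path}: missing columns {sorted(missing)}")
    meta = pd.read_csv(slide_meta_path)
    if "slide" not in meta.columns or "um_per_px" not in meta.columns:
        raise FormatError(f"{slide_meta_path}: needs 'slide' and 'um_per_px' columns")
    meta = meta.set_index("slide")
    for m in markers:
        col = cells[m]
        if col.dtype == object:
            col = col.astype(str).str.lower().map({"true": True, "false": False})
            if col.isna().any():
                raise FormatError(f"{cells_path}: non-boolean value in marker {m!r}")
        cells[m] = col.astype(bool)
    return CellTable(cells, meta, markers=markers)


def write_cell_table(ct: CellTable, cells_path, slide_meta_path) -> None:
    with _open(cells_path, "wt") as fh:
        ct.cells.to_csv(fh, index=False)
    with _open(slide_meta_path, "wt") as fh:
        ct.slide_meta.to_csv(fh, index=True)


# ------------------------------------------------------------------ YAML ----

def load_yaml(path) -> dict:
    with _open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: top-level YAML must be a mapping")
    return data


def dump_yaml(data: dict, path) -> None:
    with _open(path, "wt") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
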