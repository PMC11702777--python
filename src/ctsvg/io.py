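"""Readers and writers for every external format the pipeline touches.

Supported inputs: Space Ranger 2 µm feature-barcode matrices (MatrixMarket
triplet directory or 10x-schema HDF5), tissue-position tables (parquet or
CSV), scale-factor JSON, nuclei segmentation polygons as GeoJSON
(RFC 7946), generic count-matrix + coordinate-table pairs, and Xenium-style
transcript tables.  All geometry is kept in full-resolution pixel units; no
reader rescales coordinates.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from shapely.geometry import Polygon, mapping, shape
from shapely.validation import explain_validity

from .containers import (
    UNASSIGNED,
    CellMatrix,
    CountTable,
    NucleusPolygon,
    SquareGrid,
    TranscriptTable,
)

logger = logging.getLogger(__name__)

POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


# ---------------------------------------------------------------------------
# feature-barcode matrices
# ---------------------------------------------------------------------------

def _read_mtx_dir(path: Path) -> CountTable:
    matrix = scipy.io.mmread(str(path / "matrix.mtx"))
    features = pd.read_csv(path / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)
    # features.tsv may carry (id, symbol, type); the symbol column is used
    genes = features.iloc[:, 1] if features.shape[1] > 1 else features.iloc[:, 0]
    data = np.asarray(matrix.todense() if sp.issparse(matrix) else matrix)
    if sp.issparse(matrix):
        values = matrix.tocoo().data
    else:
        values = data.ravel()
    if not np.allclose(values, np.round(values)):
        raise ValueError("non-integer counts in matrix")
    return CountTable(
        genes=pd.Index(genes.astype(str)),
        units=pd.Index(barcodes.iloc[:, 0].astype(str)),
        counts=sp.csr_matrix(matrix, dtype=np.int64),
    )


def _read_10x_h5(path: Path) -> CountTable:
    import h5py

    with h5py.File(path, "r") as f:
        grp = f["matrix"]
        data = grp["data"][:]
        if not np.allclose(data, np.round(data)):
            raise ValueError("non-integer counts in matrix")
        mat = sp.csc_matrix(
            (data.astype(np.int64), grp["indices"][:], grp["indptr"][:]),
            shape=tuple(grp["shape"][:]),
        )
        genes = [g.decode() for g in grp["features"]["name"][:]]
        barcodes = [b.decode() for b in grp["barcodes"][:]]
    return CountTable(genes=pd.Index(genes), units=pd.Index(barcodes), counts=sp.csr_matrix(mat))


def read_count_matrix(path) -> CountTable:
    """Read a feature-barcode matrix from an MTX directory or a 10x HDF5 file."""
    path = Path(path)
    if path.is_dir():
        return _read_mtx_dir(path)
    if path.suffix in {".h5", ".hdf5"}:
        return _read_10x_h5(path)
    raise ValueError(f"unrecognised matrix input: {path}")


def write_count_matrix(table: CountTable, outdir) -> None:
    """Write a CountTable as an MTX triplet directory (matrix/features/barcodes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(table.counts), field="integer")
    pd.DataFrame({0: table.genes, 1: table.genes, 2: "Gene Expression"}).to_csv(
        outdir / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(table.units).to_csv(outdir / "barcodes.tsv", sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Visium HD
# ---------------------------------------------------------------------------

def read_positions(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        pos = pd.read_parquet(path)
    else:
        pos = pd.read_csv(path)
        if "barcode" not in pos.columns:  # headerless legacy dialect
            pos = pd.read_csv(path, header=None, names=POSITION_COLUMNS)
    missing = set(POSITION_COLUMNS) - set(pos.columns)
    if missing:
        raise ValueError(f"positions file missing columns: {sorted(missing)}")
    return pos


def read_visiumhd(matrix_path, positions_path, scalefactors_path, bin_size_um: float = 2.0):
    """Load Space Ranger 2 µm output into a (SquareGrid, CountTable) pair.

    Pixel row maps to ``y`` and pixel column to ``x``.  The square side in
    pixels is ``bin_size_um / microns_per_pixel`` from the scale-factor JSON.
    """
    counts = read_count_matrix(matrix_path)
    pos = read_positions(positions_path).set_index("barcode")
    missing = counts.units.difference(pos.index)
    if len(missing):
        raise ValueError(
            "barcodes present in matrix but absent from positions: "
            + ", ".join(map(str, missing[:10]))
        )
    pos = pos.loc[counts.units]
    with open(scalefactors_path) as f:
        scale = json.load(f)
    size_px = float(bin_size_um) / float(scale["microns_per_pixel"])
    squares = pd.DataFrame(
        {
            "x": pos["pxl_col_in_fullres"].to_numpy(dtype=float),
            "y": pos["pxl_row_in_fullres"].to_numpy(dtype=float),
            "row": pos["array_row"].to_numpy(dtype=np.int64),
            "col": pos["array_col"].to_numpy(dtype=np.int64),
        },
        index=counts.units,
    )
    return SquareGrid(squares=squares, size_px=size_px), counts


def write_visiumhd(grid: SquareGrid, counts: CountTable, outdir, bin_size_um: float = 2.0) -> None:
    """Write the Space Ranger-style fixture tree (MTX dir + positions CSV + JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_count_matrix(counts, outdir / "matrix")
    pos = pd.DataFrame(
        {
            "barcode": grid.squares.index,
            "in_tissue": 1,
            "array_row": grid.squares["row"].to_numpy(),
            "array_col": grid.squares["col"].to_numpy(),
            "pxl_row_in_fullres": grid.squares["y"].to_numpy(),
            "pxl_col_in_fullres": grid.squares["x"].to_numpy(),
        }
    )
    pos.to_csv(outdir / "tissue_positions.csv", index=False)
    with open(outdir / "scalefactors_json.json", "w") as f:
        json.dump({"microns_per_pixel": bin_size_um / grid.size_px}, f)


# ---------------------------------------------------------------------------
# nuclei GeoJSON
# ---------------------------------------------------------------------------

def read_nuclei_geojson(path) -> list[NucleusPolygon]:
    """Load nucleus polygons from a GeoJSON FeatureCollection.

    Non-polygon geometries are skipped and self-intersecting contours rejected,
    both with a logged warning; interior rings are dropped (nuclei are simple
    blobs).  Nucleus ids are taken from a feature ``id``/property when integer,
    else assigned by file order.
    """
    with open(path) as f:
        gj = json.load(f)
    features = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    nuclei: list[NucleusPolygon] = []
    for k, feat in enumerate(features):
        geom = feat.get("geometry", feat)
        if geom is None or geom.get("type") != "Polygon":
            logger.warning("skipping non-polygon geometry at feature %d", k)
            continue
        poly = Polygon(shape(geom).exterior)  # exterior ring only
        if not poly.is_valid or poly.area <= 0:
            logger.warning(
                "rejecting invalid contour at feature %d: %s", k, explain_validity(poly)
            )
            continue
        nid = feat.get("id", feat.get("properties", {}).get("id", k) if feat.get("properties") else k)
        try:
            nid = int(nid)
        except (TypeError, ValueError):
            nid = k
        nuclei.append(NucleusPolygon(nucleus_id=nid, polygon=poly))
    return nuclei


def write_nuclei_geojson(nuclei: list[NucleusPolygon], path) -> None:
    features = [
        {
            "type": "Feature",
            "id": n.nucleus_id,
            "properties": {"id": n.nucleus_id},
            "geometry": mapping(n.polygon),
        }
        for n in nuclei
    ]
    with open(path, "w") as f:
        json.dump({"type": "FeatureCollection", "features": features}, f)


# ---------------------------------------------------------------------------
# generic mode + cell matrices
# ---------------------------------------------------------------------------

def read_generic(counts_path, coords_path) -> CellMatrix:
    """Generic-mode input: a gene x cell count matrix plus a cell coordinate table.

    ``counts_path`` is an MTX directory or a CSV with gene rows and cell-id
    columns; ``coords_path`` a CSV with columns (cell, x, y).  Cell ids must
    match one-to-one across the two inputs.
    """
    counts_path = Path(counts_path)
    if counts_path.is_dir():
        table = read_count_matrix(counts_path)
    else:
        df = pd.read_csv(counts_path, index_col=0)
        values = df.to_numpy()
        if not np.allclose(values, np.round(values)):
            raise ValueError("non-integer counts in matrix")
        table = CountTable(
            genes=pd.Index(df.index.astype(str)),
            units=pd.Index(df.columns.astype(str)),
            counts=sp.csr_matrix(values.astype(np.int64)),
        )
    coords = pd.read_csv(coords_path)
    coords.columns = [c.lower() for c in coords.columns]
    cell_col = "cell" if "cell" in coords.columns else coords.columns[0]
    coords = coords.rename(columns={cell_col: "cell"}).set_index("cell")
    coords.index = coords.index.astype(str)
    if coords.index.has_duplicates:
        raise ValueError("duplicate cell ids in coordinate table")
    if set(coords.index) != set(table.units):
        extra = sorted(set(coords.index).symmetric_difference(table.units))
        raise ValueError(f"cell ids do not match between counts and coordinates: {extra[:10]}")
    coords = coords.loc[table.units]
    return CellMatrix(genes=table.genes, cells=coords[["x", "y"]].copy(), counts=table.counts)


def write_cell_matrix(cells: CellMatrix, outdir) -> None:
    """Write an aggregated cell matrix: MTX dir + cell metadata TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_count_matrix(
        CountTable(genes=cells.genes, units=cells.cells.index.astype(str), counts=cells.counts),
        outdir / "matrix",
    )
    meta = cells.cells.copy()
    if cells.labels is not None:
        meta["cluster"] = np.asarray(cells.labels)
    meta.to_csv(outdir / "cells.tsv", sep="\t", index_label="cell")


def read_cell_matrix(outdir) -> CellMatrix:
    outdir = Path(outdir)
    table = read_count_matrix(outdir / "matrix")
    meta = pd.read_csv(outdir / "cells.tsv", sep="\t", index_col="cell")
    meta.index = meta.index.astype(str)
    meta = meta.loc[table.units]
    labels = meta.pop("cluster").to_numpy() if "cluster" in meta.columns else None
    return CellMatrix(genes=table.genes, cells=meta, counts=table.counts, labels=labels)


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

def read_transcripts(path) -> TranscriptTable:
    """Read a Xenium-style transcript table (CSV or parquet: x, y, gene[, cell_id])."""
    path = Path(path)
    df = pd.read_parquet(path) if path.suffix == ".parquet" else pd.read_csv(path)
    df = df.rename(columns={"cell_id": "gold_cell"})
    return TranscriptTable(table=df)


def write_transcripts(transcripts: TranscriptTable, path) -> None:
    path = Path(path)
    df = transcripts.table.rename(columns={"gold_cell": "cell_id"})
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: name <TAB> description <TAB> gene..."""
    sets: dict[str, list[str]] = {}
    with open(path) as f:
        for line in f:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
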