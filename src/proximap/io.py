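"""Input/output and preprocessing for single-molecule spatial transcript tables.

The canonical in-memory representation of a transcript table is a
:class:`pandas.DataFrame` with columns ``cell`` (opaque identifier), ``gene``
(panel symbol), ``x``/``y`` (micrometres), and ``z`` (integer z-plane index,
``0`` for single-plane data). Region assignment adds ``region`` (one of
``Nuc``/``PN``/``Cyt``/``CP``) and ``in_nucleus`` (bool).

Cell geometry is a mapping ``cell_id -> CellGeometry`` holding shapely
polygons for the cell and nucleus boundaries in the same micrometre frame.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as _geojson_shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger("proximap")

#: Subcellular region labels, in fixed priority order (used for tie-breaks).
REGIONS = ("Nuc", "PN", "Cyt", "CP")

CANONICAL_COLUMNS = ("cell", "gene", "x", "y", "z")


class SchemaError(ValueError):
    """A required column or cell record is missing or malformed."""


class ParseError(ValueError):
    """A field could not be parsed; the message names the offending row."""


@dataclass(frozen=True)
class ColumnMap:
    """Maps caller column names onto the canonical transcript schema."""

    cell: str = "cell"
    gene: str = "gene"
    x: str = "x"
    y: str = "y"
    z: str | None = "z"


@dataclass(frozen=True)
class AnnotationConfig:
    """Widths (micrometres) of the peri-nuclear band and cell-periphery rim.

    ``pn_halfwidth`` extends the peri-nuclear region that many micrometres on
    *either* side of the nuclear membrane; ``cp_width`` is the depth of the
    cell-periphery rim inside the cell membrane.
    """

    pn_halfwidth: float = 2.5
    cp_width: float = 4.0

    def __post_init__(self) -> None:
        if self.pn_halfwidth <= 0 or self.cp_width <= 0:
            raise ValueError("annotation widths must be strictly positive")


@dataclass(frozen=True)
class CellGeometry:
    """Cell and nucleus boundary polygons for one cell (shared frame)."""

    cell_id: object
    cell_boundary: BaseGeometry
    nucleus_boundary: BaseGeometry

    def __post_init__(self) -> None:
        if self.nucleus_boundary.area >= self.cell_boundary.area:
            raise ValueError(
                f"cell {self.cell_id!r}: nucleus area must be smaller than cell area"
            )


def load_transcripts(
    path,
    columns: ColumnMap | Mapping[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Load a transcript table from CSV/TSV (gzip accepted).

    Parameters
    ----------
    path
        Delimited text file, one row per detected transcript.
    columns
        Mapping from canonical names to the file's column names.
    sep
        Field separator; inferred from the extension when omitted
        (``.tsv``/``.txt`` -> tab, else comma).
    """
    if columns is None:
        columns = ColumnMap()
    elif isinstance(columns, Mapping):
        columns = ColumnMap(**columns)
    if sep is None:
        stem = str(path)
        if stem.endswith(".gz"):
            stem = stem[:-3]
        sep = "\t" if stem.endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep)

    out = pd.DataFrame(index=raw.index)
    for canon in ("cell", "gene", "x", "y"):
        src = getattr(columns, canon)
        if src not in raw.columns:
            raise SchemaError(f"missing required column {src!r} (maps to {canon!r})")
        out[canon] = raw[src]
    if columns.z is not None and columns.z in raw.columns:
        out["z"] = raw[columns.z]
    else:
        out["z"] = 0

    for coord in ("x", "y"):
        vals = pd.to_numeric(out[coord], errors="coerce")
        bad = ~np.isfinite(vals.to_numpy(dtype=float))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(f"non-finite {coord!r} coordinate at row {row}")
        out[coord] = vals.astype(float)
    zvals = pd.to_numeric(out["z"], errors="coerce")
    if zvals.isna().any() or (zvals < 0).any():
        row = int(np.flatnonzero(zvals.isna() | (zvals < 0))[0])
        raise ParseError(f"invalid z-plane index at row {row}")
    out["z"] = zvals.astype(int)
    out["gene"] = out["gene"].astype(str)
    return out.reset_index(drop=True)


def load_geometry(path) -> dict:
    """Load cell/nucleus boundaries from a GeoJSON FeatureCollection.

    Each Feature carries properties ``cell_id`` and ``role`` (``"cell"`` or
    ``"nucleus"``); both roles must be present for every cell.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        doc = json.load(fh)
    polys: dict[object, dict[str, BaseGeometry]] = {}
    for feat in doc.get("features", []):
        props = feat.get("properties", {})
        cid, role = props.get("cell_id"), props.get("role")
        if role not in ("cell", "nucleus"):
            raise SchemaError(f"feature for cell {cid!r} has invalid role {role!r}")
        polys.setdefault(cid, {})[role] = _geojson_shape(feat["geometry"])
    geoms = {}
    for cid, d in polys.items():
        if "cell" not in d or "nucleus" not in d:
            raise SchemaError(f"cell {cid!r} is missing a cell or nucleus boundary")
        geoms[cid] = CellGeometry(cid, d["cell"], d["nucleus"])
    return geoms


def load_cell_meta(path, sep: str | None = None) -> pd.DataFrame:
    """Load per-cell metadata (cell_id, optional cell_type, centroids)."""
    if sep is None:
        sep = "\t" if str(path).rstrip(".gz").endswith((".tsv", ".txt")) else ","
    meta = pd.read_csv(path, sep=sep)
    if "cell_id" not in meta.columns:
        raise SchemaError("missing required column 'cell_id'")
    if meta["cell_id"].duplicated().any():
        raise SchemaError("duplicate cell_id in metadata")
    return meta


def filter_cells(
    table: pd.DataFrame, min_per_plane: int = 0, min_total: int = 0
) -> pd.DataFrame:
    """Drop cells lacking a z-plane with ``min_per_plane`` transcripts or
    fewer than ``min_total`` transcripts overall.

    Idempotent; returns the retained rows in their original order.
    """
    if min_per_plane < 0 or min_total < 0:
        raise ValueError("thresholds must be >= 0")
    if table.empty or (min_per_plane == 0 and min_total == 0):
        return table
    per_plane = table.groupby(["cell", "z"], sort=False).size()
    best_plane = per_plane.groupby(level="cell").max()
    totals = table.groupby("cell", sort=False).size()
    keep = totals.index[(best_plane.reindex(totals.index) >= min_per_plane)
                        & (totals >= min_total)]
    removed = totals.index.size - keep.size
    if removed:
        logger.info("filter_cells: removed %d of %d cells", removed, totals.index.size)
    return table[table["cell"].isin(set(keep))].copy()


def assign_regions(
    table: pd.DataFrame,
    geometry: Mapping[object, CellGeometry],
    cfg: AnnotationConfig | None = None,
) -> pd.DataFrame:
    """Label each transcript with a subcellular region.

    A transcript is ``PN`` when its distance to the nuclear membrane is at
    most ``pn_halfwidth`` (on either side), else ``Nuc`` when inside the
    nucleus, else ``CP`` when within ``cp_width`` of the cell membrane, else
    ``Cyt``. Transcripts falling outside their cell boundary are labelled by
    the nearest region (PN band or CP) with a warning.

    Adds ``region`` and ``in_nucleus`` columns; deterministic.
    """
    cfg = cfg or AnnotationConfig()
    region = np.empty(len(table), dtype=object)
    in_nuc = np.zeros(len(table), dtype=bool)
    n_outside = 0
    for cid, idx in table.groupby("cell", sort=False).indices.items():
        if cid not in geometry:
            raise SchemaError(f"no geometry for cell {cid!r}")
        geom = geometry[cid]
        pts = shapely.points(
            table["x"].to_numpy()[idx], table["y"].to_numpy()[idx]
        )
        nuc_b = geom.nucleus_boundary.exterior
        cell_b = geom.cell_boundary.exterior
        d_nuc = shapely.distance(nuc_b, pts)
        d_cell = shapely.distance(cell_b, pts)
        inside_nuc = shapely.covers(geom.nucleus_boundary, pts)
        inside_cell = shapely.covers(geom.cell_boundary, pts)

        lab = np.where(
            d_nuc <= cfg.pn_halfwidth,
            "PN",
            np.where(inside_nuc, "Nuc", np.where(d_cell <= cfg.cp_width, "CP", "Cyt")),
        )
        # Points outside the cell: nearest region is the PN band or the rim.
        stray = ~inside_cell
        if stray.any():
            n_outside += int(stray.sum())
            lab[stray] = np.where(d_nuc[stray] <= cfg.pn_halfwidth, "PN", "CP")
        region[idx] = lab
        in_nuc[idx] = inside_nuc
    if n_outside:
        logger.warning(
            "assign_regions: %d transcripts outside their cell boundary; "
            "labelled by nearest region",
            n_outside,
        )
    out = table.copy()
    out["region"] = region
    out["in_nucleus"] = in_nuc
    return out


def permute_gene_labels(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Shuffle gene labels uniformly at random within each cell.

    The per-cell multiset of gene labels, the coordinates, z-planes and cell
    membership are all preserved, so the permuted table retains the spatial
    texture of the original while destroying gene-gene relationships. Used
    as the randomized baseline for false-positive-rate estimation.
    """
    rng = np.random.default_rng(seed)
    genes = table["gene"].to_numpy(dtype=object).copy()
    for _, idx in table.groupby("cell", sort=False).indices.items():
        genes[idx] = genes[idx[rng.permutation(len(idx))]]
    out = table.copy()
    out["gene"] = genes
    return out


def gene_panel(table: pd.DataFrame) -> list[str]:
    """Sorted list of gene symbols present in the table."""
    return sorted(table["gene"].unique())


def blank_genes(panel: Iterable[str], prefix: str = "Blank") -> set[str]:
    """Genes whose names mark them as blank (no-target) barcodes."""
    return {g for g in panel if g.startswith(prefix)}


def write_tsv(df: pd.DataFrame, path, params: Mapping[str, object] | None = None) -> None:
    """Write a TSV with commented header lines recording version and params."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# proximap {__version__}\n")
        for key, val in (params or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv` (comment lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")
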