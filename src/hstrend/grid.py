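"""Grid data model and raster/table I/O.

Every raster in the pipeline lives on a shared :class:`Grid` — a regular
lattice with a fixed cell size, indexed 0-based, row-major, with row 0 the
northernmost row.  Cell ``cell_id = row * n_cols + col``.  Coordinates refer
to cell centroids; y decreases with increasing row.

Rasters are interchanged as plain-text ESRI ASCII grids (``.asc``), one file
per layer, so the whole pipeline runs without a geospatial stack.  A
predictor time series is a directory of ``.asc`` files plus a JSON manifest
naming years and predictors.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("hstrend")

DEFAULT_NODATA = -9999.0

#: IUCN red-list codes accepted in trait tables.
IUCN_CODES = frozenset({"LC", "NT", "VU", "EN", "CR", "DD", "NE"})

TRAIT_COLUMNS = (
    "group",
    "diet",
    "habitat",
    "climate_affinity",
    "activity",
    "feeding",
    "photosynthesis",
    "reproduction",
)


class GridMismatchError(ValueError):
    """Raised when rasters that must share a grid do not."""


@dataclass(frozen=True)
class Grid:
    """A regular raster lattice shared by all layers of an analysis.

    Parameters
    ----------
    n_rows, n_cols
        Lattice dimensions; both >= 1.
    origin_x, origin_y
        Map coordinates of the *north-west corner* of the grid.
    cell_size
        Edge length of a (square) cell in map units; > 0.
    valid_mask
        Boolean array of shape ``(n_rows, n_cols)``; True where the cell is
        part of the study area.  Defaults to all-valid.
    """

    n_rows: int
    n_cols: int
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0
    valid_mask: np.ndarray = field(default=None, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        mask = self.valid_mask
        if mask is None:
            mask = np.ones((self.n_rows, self.n_cols), dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool).reshape(self.n_rows, self.n_cols)
        mask.setflags(write=False)
        object.__setattr__(self, "valid_mask", mask)

    # -- indexing ---------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def valid_cell_ids(self) -> np.ndarray:
        """Cell ids of all valid cells, ascending."""
        return np.flatnonzero(self.valid_mask.ravel())

    def rowcol_to_cell(self, row, col):
        return np.asarray(row) * self.n_cols + np.asarray(col)

    def cell_to_rowcol(self, cell_id):
        cell_id = np.asarray(cell_id)
        return cell_id // self.n_cols, cell_id % self.n_cols

    def cell_centroid_xy(self, cell_id):
        """Map coordinates of cell centroids (y decreasing with row)."""
        row, col = self.cell_to_rowcol(cell_id)
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y - (row + 0.5) * self.cell_size
        return x, y

    def xy_to_cell(self, x, y):
        """Snap points to containing cells (half-open cells: a point on a
        shared edge belongs to the cell to the right / below).

        Returns -1 for points outside the grid extent.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - y) / self.cell_size).astype(int)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        cell = np.where(inside, row * self.n_cols + np.clip(col, 0, self.n_cols - 1), -1)
        return cell

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and np.isclose(self.origin_x, other.origin_x)
            and np.isclose(self.origin_y, other.origin_y)
            and np.isclose(self.cell_size, other.cell_size)
        )


@dataclass
class RasterLayer:
    """Per-cell real values on a :class:`Grid`, with a nodata sentinel.

    ``values`` is a flat float array of length ``grid.n_cells``; invalid
    cells carry the nodata value.
    """

    grid: Grid
    values: np.ndarray
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size != self.grid.n_cells:
            raise ValueError(
                f"raster has {v.size} values, grid has {self.grid.n_cells} cells"
            )
        v = v.copy()
        v[~self.grid.valid_mask.ravel()] = self.nodata
        self.values = v

    def as_2d(self) -> np.ndarray:
        return self.values.reshape(self.grid.n_rows, self.grid.n_cols)

    def valid_values(self) -> np.ndarray:
        """Values over valid cells, in cell-id order."""
        return self.values[self.grid.valid_cell_ids()]

    def is_missing(self) -> np.ndarray:
        """Boolean per cell: nodata (invalid or masked)."""
        return self.values == self.nodata

    @classmethod
    def full(cls, grid: Grid, fill: float, nodata: float = DEFAULT_NODATA) -> "RasterLayer":
        return cls(grid, np.full(grid.n_cells, fill, dtype=float), nodata)

    @classmethod
    def from_valid(cls, grid: Grid, valid_values: np.ndarray,
                   nodata: float = DEFAULT_NODATA) -> "RasterLayer":
        """Build a layer from values given for valid cells only."""
        v = np.full(grid.n_cells, nodata, dtype=float)
        v[grid.valid_cell_ids()] = np.asarray(valid_values, dtype=float)
        return cls(grid, v, nodata)


@dataclass
class PredictorStack:
    """Annual environmental predictor time series on a shared grid.

    ``layers[(year, predictor)]`` maps to a :class:`RasterLayer`.  Years are
    strictly increasing and consecutive; the predictor set is identical in
    every year.  Binary predictors (e.g. annual fire presence) take values
    in {0, 1} on valid cells.
    """

    grid: Grid
    years: list
    predictor_names: list
    layers: dict

    def __post_init__(self) -> None:
        yrs = list(self.years)
        if any(b - a != 1 for a, b in zip(yrs, yrs[1:])):
            raise ValueError("years must be strictly increasing and consecutive")
        for y in yrs:
            for p in self.predictor_names:
                if (y, p) not in self.layers:
                    raise ValueError(f"missing layer for year {y}, predictor {p!r}")
                if not self.layers[(y, p)].grid.same_geometry(self.grid):
                    raise GridMismatchError(f"grid mismatch for year {y}, predictor {p!r}")
        self.years = yrs

    def layer(self, year, predictor) -> RasterLayer:
        return self.layers[(year, predictor)]

    def array(self) -> np.ndarray:
        """Dense array of shape (n_years, n_predictors, n_valid_cells)."""
        vid = self.grid.valid_cell_ids()
        out = np.empty((len(self.years), len(self.predictor_names), vid.size))
        for i, y in enumerate(self.years):
            for j, p in enumerate(self.predictor_names):
                out[i, j] = self.layers[(y, p)].values[vid]
        return out


@dataclass
class OccurrenceSet:
    """Per-species deduplicated presence cells with optional traits.

    ``cells`` is a set of valid cell ids; traits map trait names to
    categories; conservation status codes are IUCN red-list categories.
    """

    species_id: str
    cells: set
    traits: dict = field(default_factory=dict)
    status_regional: str = "NE"
    status_european: str = "NE"

    def __post_init__(self) -> None:
        self.cells = set(int(c) for c in self.cells)
        for code in (self.status_regional, self.status_european):
            if code not in IUCN_CODES:
                raise ValueError(f"unknown IUCN code {code!r}")

    @property
    def n_records(self) -> int:
        return len(self.cells)

    def sorted_cells(self) -> np.ndarray:
        return np.array(sorted(self.cells), dtype=int)


# ---------------------------------------------------------------------------
# ASCII-grid raster I/O
# ---------------------------------------------------------------------------

def write_ascii_grid(layer: RasterLayer, path: str) -> None:
    """Write a layer as an ESRI ASCII grid (plain text)."""
    g = layer.grid
    yll = g.origin_y - g.n_rows * g.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.origin_x!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {g.cell_size!r}\n")
        fh.write(f"NODATA_value {layer.nodata!r}\n")
        np.savetxt(fh, layer.as_2d(), fmt="%.9g")


def read_ascii_grid(path: str) -> RasterLayer:
    """Read an ESRI ASCII grid; validity is inferred from nodata cells."""
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"):
                header[key] = float(val)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        data = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data shape {data.shape} != header ({n_rows},{n_cols})")
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    cell = header["cellsize"]
    grid = Grid(
        n_rows=n_rows,
        n_cols=n_cols,
        origin_x=header.get("xllcorner", 0.0),
        origin_y=header.get("yllcorner", 0.0) + n_rows * cell,
        cell_size=cell,
        valid_mask=data != nodata,
    )
    return RasterLayer(grid, data.ravel(), nodata=nodata)


def stack_layer_filename(year, predictor: str) -> str:
    return f"{year}_{predictor}.asc"


def write_raster_stack(stack: PredictorStack, out_dir: str) -> None:
    """Write one ``.asc`` per (year, predictor) plus a JSON manifest."""
    os.makedirs(out_dir, exist_ok=True)
    files = {}
    for y in stack.years:
        for p in stack.predictor_names:
            fn = stack_layer_filename(y, p)
            write_ascii_grid(stack.layers[(y, p)], os.path.join(out_dir, fn))
            files[f"{y}/{p}"] = fn
    manifest = {
        "years": [int(y) for y in stack.years],
        "predictors": list(stack.predictor_names),
        "files": files,
    }
    with open(os.path.join(out_dir, "stack.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_raster_stack(paths, year_labels, predictor_labels) -> PredictorStack:
    """Assemble a :class:`PredictorStack` from per-layer ASCII grids.

    ``paths`` is year-major: all predictors of the first year, then the
    second, etc.  All files must share grid geometry; a mismatch is a hard
    error naming the offending file.
    """
    years = list(year_labels)
    preds = list(predictor_labels)
    if len(paths) != len(years) * len(preds):
        raise ValueError(
            f"{len(paths)} files cannot cover {len(years)} years x {len(preds)} predictors"
        )
    layers = {}
    ref_grid = None
    it = iter(paths)
    for y in years:
        for p in preds:
            path = next(it)
            layer = read_ascii_grid(path)
            if ref_grid is None:
                ref_grid = layer.grid
            elif not layer.grid.same_geometry(ref_grid):
                raise GridMismatchError(f"grid mismatch: {path}")
            elif not np.array_equal(layer.grid.valid_mask, ref_grid.valid_mask):
                # harmonize nodata: a cell is valid only if valid everywhere
                combined = layer.grid.valid_mask & ref_grid.valid_mask
                ref_grid = Grid(ref_grid.n_rows, ref_grid.n_cols, ref_grid.origin_x,
                                ref_grid.origin_y, ref_grid.cell_size, combined)
            layers[(y, p)] = layer
    layers = {
        k: RasterLayer(ref_grid, v.values, nodata=v.nodata) for k, v in layers.items()
    }
    return PredictorStack(ref_grid, years, preds, layers)


def read_stack_dir(stack_dir: str) -> PredictorStack:
    """Read a stack written by :func:`write_raster_stack`."""
    with open(os.path.join(stack_dir, "stack.json")) as fh:
        manifest = json.load(fh)
    years = manifest["years"]
    preds = manifest["predictors"]
    paths = [
        os.path.join(stack_dir, manifest["files"][f"{y}/{p}"])
        for y in years
        for p in preds
    ]
    return read_raster_stack(paths, years, preds)


# ---------------------------------------------------------------------------
# Occurrence / trait tables
# ---------------------------------------------------------------------------

def cell_centroids(grid: Grid):
    """(cell_id, x, y) for every valid cell — the background-point lattice."""
    ids = grid.valid_cell_ids()
    x, y = grid.cell_centroid_xy(ids)
    return list(zip(ids.tolist(), np.asarray(x).tolist(), np.asarray(y).tolist()))


def read_traits(path: str) -> dict:
    """Read the per-species trait/status table (CSV keyed by species_id)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    out = {}
    for _, row in df.iterrows():
        traits = {c: row[c] for c in TRAIT_COLUMNS if c in df.columns and row[c]}
        out[row["species_id"]] = {
            "traits": traits,
            "status_regional": row.get("status_regional", "") or "NE",
            "status_european": row.get("status_european", "") or "NE",
        }
    return out


def read_occurrences(path: str, grid: Grid, min_records: int = 15,
                     traits_path: str | None = None):
    """Read species occurrences, snap to grid cells, deduplicate and filter.

    The CSV needs columns ``species_id`` and either ``x,y`` (map units,
    snapped by floor division to the containing cell) or ``cell_id``.
    Records outside the extent or on invalid cells are dropped with a logged
    count; species with fewer than ``min_records`` distinct cells are
    excluded (the minimum-sample filter for reliable models).

    Returns a list of :class:`OccurrenceSet` sorted by species id.
    """
    df = pd.read_csv(path)
    if "cell_id" in df.columns:
        cells = df["cell_id"].to_numpy(dtype=int)
        oob = (cells < 0) | (cells >= grid.n_cells)
        cells = np.where(oob, -1, cells)
    elif {"x", "y"} <= set(df.columns):
        cells = grid.xy_to_cell(df["x"].to_numpy(float), df["y"].to_numpy(float))
    else:
        raise ValueError("occurrence CSV needs columns species_id + (x,y or cell_id)")

    n_oob = int((cells == -1).sum())
    if n_oob:
        logger.warning("%d occurrence records outside grid extent dropped", n_oob)
    valid = grid.valid_mask.ravel()
    on_invalid = (cells >= 0) & ~valid[np.clip(cells, 0, grid.n_cells - 1)]
    if on_invalid.any():
        logger.warning("%d occurrence records on invalid cells dropped",
                       int(on_invalid.sum()))
    keep = (cells >= 0) & ~on_invalid

    trait_info = read_traits(traits_path) if traits_path else {}
    out = []
    for sp, sub in df.loc[keep].assign(_cell=cells[keep]).groupby("species_id"):
        cellset = set(sub["_cell"].tolist())
        if len(cellset) < min_records:
            logger.info("species %s excluded: %d < %d records", sp, len(cellset),
                        min_records)
            continue
        info = trait_info.get(str(sp), {})
        out.append(OccurrenceSet(
            species_id=str(sp),
            cells=cellset,
            traits=info.get("traits", {}),
            status_regional=info.get("status_regional", "NE"),
            status_european=info.get("status_european", "NE"),
        ))
    if not out:
        raise ValueError("no species passed ingestion filters")
    return sorted(out, key=lambda s: s.species_id)


def write_occurrences(occ_sets, grid: Grid, path: str) -> None:
    """Write occurrence sets as a ``species_id,x,y`` CSV (cell centroids)."""
    rows = []
    for sp in occ_sets:
        ids = sp.sorted_cells()
        x, y = grid.cell_centroid_xy(ids)
        for cx, cy in zip(np.atleast_1d(x), np.atleast_1d(y)):
            rows.append((sp.species_id, cx, cy))
    pd.DataFrame(rows, columns=["species_id", "x", "y"]).to_csv(path, index=False)
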