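"""Plain-text raster I/O in the ESRI ASCII grid format.

A ``.asc`` file carries one band: a six-line header (ncols, nrows,
xllcorner, yllcorner, cellsize, NODATA_value) followed by rows of
whitespace-separated values, north row first.  The NODATA value maps
bit-exactly onto the missing mask.  Coordinates are degrees; the in-memory
cell size is arcminutes, converted on the way in and out.

Category grids are written as integer-coded rasters with a sidecar CSV
legend (code, factor, label).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .layers import CategoryGrid, Grid, GridTransform

DEFAULT_NODATA = -9999.0


def write_ascii_grid(grid: Grid, path: str | Path,
                     nodata: float = DEFAULT_NODATA) -> None:
    path = Path(path)
    nrows, ncols = grid.shape
    t = grid.transform
    cell_deg = t.cell_arcmin / 60.0
    yll = t.north - nrows * cell_deg
    vals = grid.values.copy()
    vals[grid.mask] = nodata
    if np.any(vals[~grid.mask] == nodata):
        raise ValueError("unmasked cell collides with the nodata value")
    with path.open("w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {t.west!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {cell_deg!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> Grid:
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with path.open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if len(parts) == 2 and key in {"ncols", "nrows", "xllcorner",
                                           "yllcorner", "cellsize",
                                           "nodata_value"}:
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=float))
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"missing header field {req!r} in {path}")
    vals = np.vstack(rows)
    if vals.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"data shape {vals.shape} disagrees with header in {path}")
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    mask = vals == nodata
    vals = np.where(mask, np.nan, vals)
    cell_deg = header["cellsize"]
    north = header["yllcorner"] + vals.shape[0] * cell_deg
    return Grid(values=vals, mask=mask,
                transform=GridTransform(west=header["xllcorner"], north=north,
                                        cell_arcmin=cell_deg * 60.0))


def write_category_grid(cat: CategoryGrid, path: str | Path,
                        legend_path: str | Path | None = None) -> None:
    """Write an integer-coded raster plus a CSV legend next to it."""
    path = Path(path)
    as_grid = Grid(values=cat.codes.astype(float), transform=cat.transform,
                   mask=cat.mask)
    write_ascii_grid(as_grid, path)
    legend = Path(legend_path) if legend_path else path.with_suffix(".legend.csv")
    with legend.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["code", "factor", "label"])
        for code, label in enumerate(cat.labels):
            w.writerow([code, cat.factor, label])


def read_category_grid(path: str | Path,
                       legend_path: str | Path | None = None) -> CategoryGrid:
    path = Path(path)
    legend = Path(legend_path) if legend_path else path.with_suffix(".legend.csv")
    grid = read_ascii_grid(path)
    labels: list[str] = []
    factor = ""
    with legend.open() as fh:
        for row in csv.DictReader(fh):
            if int(row["code"]) != len(labels):
                raise ValueError(f"legend codes not contiguous in {legend}")
            labels.append(row["label"])
            factor = row["factor"]
    codes = np.where(grid.mask, 0, grid.values).astype(np.int16)
    return CategoryGrid(codes=codes, labels=tuple(labels), factor=factor,
                        transform=grid.transform, mask=grid.mask)
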