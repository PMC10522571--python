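"""Raster data model and layer-preparation rules.

Conventions, fixed across the package: cell-center registration, north-up row
order (row 0 is the northernmost), longitude-latitude axes, 0-based indexing.
Cell size is in arcminutes.  Missing data is carried as an explicit boolean
mask (True = missing); masked cells carry no value semantics and every
operation propagates the mask rather than fabricating values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

#: SoilGrids-standard depth intervals (cm) and the thickness weights used to
#: collapse a five-layer property stack to a single 0-100 cm average.
SOIL_DEPTH_INTERVALS = ((0, 5), (5, 15), (15, 30), (30, 60), (60, 100))
SOIL_DEPTH_WEIGHTS = np.array([5.0, 10.0, 15.0, 30.0, 40.0])

PH_CATEGORIES = ("low", "medium", "high")
TEXTURE_CATEGORIES = ("sandy", "loamy", "clayey")
N_RATE_CATEGORIES = ("low", "high")

#: Low-fertilization threshold, kg N ha^-1 yr^-1 (inclusive).
N_RATE_THRESHOLD = 30.0


@dataclass(frozen=True)
class GridTransform:
    """Georeference: west/north edge of the grid and square cell size."""

    west: float = -180.0
    north: float = 90.0
    cell_arcmin: float = 5.0

    def __post_init__(self) -> None:
        if self.cell_arcmin <= 0:
            raise ValueError("cell size must be positive")


@dataclass
class Grid:
    """A 2-D real-valued field with georeference and missing-data mask."""

    values: np.ndarray
    transform: GridTransform = field(default_factory=GridTransform)
    mask: np.ndarray | None = None  # True where missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask and values must have identical shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid(self) -> np.ndarray:
        """Boolean array of cells that carry a value."""
        return ~self.mask

    def filled(self, fill: float = np.nan) -> np.ndarray:
        out = self.values.copy()
        out[self.mask] = fill
        return out

    def like(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Grid":
        """New grid on this grid's geometry."""
        return Grid(values=values, transform=self.transform,
                    mask=self.mask.copy() if mask is None else mask)


@dataclass
class CategoryGrid:
    """A 2-D field of integer codes over a closed label set for one factor."""

    codes: np.ndarray
    labels: tuple[str, ...]
    factor: str
    transform: GridTransform = field(default_factory=GridTransform)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int16)
        if self.mask is None:
            self.mask = np.zeros(self.codes.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.codes.shape:
            raise ValueError("mask and codes must have identical shape")
        valid = self.codes[~self.mask]
        if valid.size and (valid.min() < 0 or valid.max() >= len(self.labels)):
            raise ValueError("category code outside label set")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    def label_at(self, row: int, col: int) -> str | None:
        if self.mask[row, col]:
            return None
        return self.labels[self.codes[row, col]]

    def coefficient_field(self, coefs: Mapping[str, float]) -> np.ndarray:
        """Map each unmasked cell's label to its multiplier."""
        try:
            lut = np.array([coefs[lab] for lab in self.labels], dtype=float)
        except KeyError as exc:
            raise KeyError(
                f"no coefficient for category {exc.args[0]!r} of factor {self.factor!r}"
            ) from None
        out = np.full(self.codes.shape, np.nan)
        ok = ~self.mask
        out[ok] = lut[self.codes[ok]]
        return out


@dataclass
class CropLayer:
    """One crop's yield (t/ha), harvested area (ha) and N rate (kg N/ha/yr)."""

    crop: str
    yield_grid: Grid
    area: Grid
    n_rate: Grid
    crop_type: str  # 'cereal_grains' or 'legumes'

    def __post_init__(self) -> None:
        align_check([self.yield_grid, self.area, self.n_rate])
        for g, name in ((self.yield_grid, "yield"), (self.area, "area")):
            vals = g.values[g.valid()]
            if vals.size and vals.min() < 0:
                raise ValueError(f"{name} grid for {self.crop!r} has negative values")


def align_check(grids: Sequence[Grid | CategoryGrid]) -> tuple[tuple[int, int], GridTransform]:
    """Validate that all grids share shape and georeference; return them."""
    if not grids:
        raise ValueError("no grids to align")
    shape, transform = grids[0].shape, grids[0].transform
    for g in grids[1:]:
        if g.shape != shape:
            raise ValueError(f"shape mismatch: {g.shape} vs {shape}")
        if g.transform != transform:
            raise ValueError(f"transform mismatch: {g.transform} vs {transform}")
    return shape, transform


def depth_weighted_average(
    layer_stack: Sequence[Grid], weighted: bool = True, renormalize: bool = True
) -> Grid:
    """Collapse a five-layer soil depth stack to one 0-100 cm grid.

    Weights are the interval thicknesses (5, 10, 15, 30, 40)/100; with
    ``weighted=False`` all layers count equally.  Cells where some layers are
    missing renormalize the weights over the available layers (set
    ``renormalize=False`` to mask any cell with an incomplete stack instead);
    all-missing cells stay missing.
    """
    if len(layer_stack) != len(SOIL_DEPTH_WEIGHTS):
        raise ValueError(f"expected {len(SOIL_DEPTH_WEIGHTS)} depth layers, "
                         f"got {len(layer_stack)}")
    shape, transform = align_check(layer_stack)
    w = SOIL_DEPTH_WEIGHTS if weighted else np.ones(len(layer_stack))
    vals = np.stack([g.values for g in layer_stack])
    miss = np.stack([g.mask for g in layer_stack])
    w3 = w[:, None, None] * ~miss
    wsum = w3.sum(axis=0)
    with np.errstate(invalid="ignore"):
        avg = np.where(wsum > 0,
                       np.sum(np.where(miss, 0.0, vals) * w3, axis=0) / np.where(wsum > 0, wsum, 1.0),
                       np.nan)
    if renormalize:
        out_mask = wsum == 0
    else:
        out_mask = miss.any(axis=0)
    avg = np.where(out_mask, np.nan, avg)
    return Grid(values=avg, transform=transform, mask=out_mask)


def classify_ph(ph: Grid) -> CategoryGrid:
    """Classify soil pH: low < 5.6; 5.6 <= medium <= 7.0; high > 7.0.

    Both interval endpoints belong to the medium class.  Unmasked values
    outside a plausible pH range (2-11) are rejected.
    """
    v = ph.values
    ok = ph.valid()
    if np.any((v[ok] < 2) | (v[ok] > 11)):
        raise ValueError("pH values outside plausible range 2-11")
    codes = np.zeros(v.shape, dtype=np.int16)
    codes[v >= 5.6] = 1
    codes[v > 7.0] = 2
    codes[~ok] = 0
    return CategoryGrid(codes=codes, labels=PH_CATEGORIES, factor="soil_ph",
                        transform=ph.transform, mask=ph.mask.copy())


def classify_texture(sand: Grid, clay: Grid) -> CategoryGrid:
    """Classify texture from sand/clay percent: sandy > 70% sand,
    clayey > 35% clay, loamy otherwise.  Sand + clay may not exceed 100,
    which makes the classes mutually exclusive."""
    align_check([sand, clay])
    ok = sand.valid() & clay.valid()
    s, c = sand.values, clay.values
    if np.any(s[ok] < 0) or np.any(c[ok] < 0):
        raise ValueError("negative texture fractions")
    if np.any((s + c)[ok] > 100 + 1e-9):
        raise ValueError("sand + clay exceeds 100% in some cells")
    codes = np.full(s.shape, 1, dtype=np.int16)  # loamy default
    codes[s > 70] = 0
    codes[c > 35] = 2
    codes[~ok] = 0
    return CategoryGrid(codes=codes, labels=TEXTURE_CATEGORIES,
                        factor="soil_texture", transform=sand.transform,
                        mask=~ok)


def classify_n_rate(n_rate: Grid) -> CategoryGrid:
    """Classify fertilization: low if rate <= 30 kg N/ha/yr, else high."""
    v = n_rate.values
    ok = n_rate.valid()
    if np.any(v[ok] < 0):
        raise ValueError("negative N application rates")
    codes = np.where(v > N_RATE_THRESHOLD, 1, 0).astype(np.int16)
    codes[~ok] = 0
    return CategoryGrid(codes=codes, labels=N_RATE_CATEGORIES, factor="n_rate",
                        transform=n_rate.transform, mask=n_rate.mask.copy())


def upscale_mean(fine: Grid, block: int) -> Grid:
    """Aggregate by block-averaging, excluding missing cells.

    Each coarse cell is the mean of the valid fine cells in its block; a block
    with no valid cell becomes missing.  Dimensions not divisible by the block
    size are padded with missing cells on the south/east edges.  The coarse
    cell size is the fine cell size times the block factor.
    """
    if block < 1:
        raise ValueError("block factor must be >= 1")
    nr, nc = fine.shape
    pr, pc = (-nr) % block, (-nc) % block
    vals = np.pad(fine.values, ((0, pr), (0, pc)), constant_values=np.nan)
    miss = np.pad(fine.mask, ((0, pr), (0, pc)), constant_values=True)
    R, C = vals.shape[0] // block, vals.shape[1] // block
    v4 = vals.reshape(R, block, C, block)
    m4 = miss.reshape(R, block, C, block)
    cnt = (~m4).sum(axis=(1, 3))
    tot = np.where(m4, 0.0, v4).sum(axis=(1, 3))
    out_mask = cnt == 0
    coarse = np.where(out_mask, np.nan, tot / np.where(cnt == 0, 1, cnt))
    t = fine.transform
    return Grid(values=coarse, mask=out_mask,
                transform=GridTransform(west=t.west, north=t.north,
                                        cell_arcmin=t.cell_arcmin * block))
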