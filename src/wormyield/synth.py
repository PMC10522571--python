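"""Synthetic global-style input layers with a known-truth mode.

The generator emulates the statistical structure of the real data products
the pipeline consumes, at whatever grid size is requested:

* earthworm abundance: log-normal, parameterized so most cells fall below
  100 individuals m^-2 (the 'low density' threshold of the underlying
  meta-analysis), with a configurable fraction of cells masked as unsampled;
* soil pH: spatially smooth fields per depth layer (white noise blurred with
  a Gaussian kernel), clipped to a plausible range;
* texture: smooth sand/clay percent fields constrained to sand + clay <= 95
  so every textural class occurs;
* N application rate: a two-component (low/high) mixture per crop so both
  fertilization classes are exercised;
* crops: four cereals (wheat, rice, maize, barley) and two legumes
  (soybean, dry bean) with log-normal yields and harvested areas;
* regions: a partition of the grid into eight contiguous blocks standing in
  for the continental-scale agricultural regions.

``generate_with_truth`` constructs observed yields as baseline * (1 + E)
from drawn baseline (earthworm-free) yields, so the exact attributable
production is known and the full pipeline can be checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .aggregate import DEFAULT_REGION_NAMES, RegionMap
from .effect import EffectParams, earthworm_effect
from .layers import (
    CategoryGrid,
    CropLayer,
    Grid,
    GridTransform,
    classify_ph,
    classify_texture,
    depth_weighted_average,
)

DEFAULT_CROPS = (
    ("wheat", "cereal_grains"),
    ("rice", "cereal_grains"),
    ("maize", "cereal_grains"),
    ("barley", "cereal_grains"),
    ("soybean", "legumes"),
    ("dry_bean", "legumes"),
)


@dataclass
class WorldConfig:
    """Parameters of the synthetic world; defaults emulate the real layers."""

    shape: tuple[int, int] = (100, 100)
    cell_arcmin: float = 5.0
    seed: int = 0
    crops: Sequence[tuple[str, str]] = DEFAULT_CROPS
    # log-normal abundance: median exp(mu) ~ 30 ind/m2, long right tail
    abundance_mu: float = 3.4
    abundance_sigma: float = 1.2
    ph_mean: float = 6.2
    ph_sd: float = 0.9
    ph_smoothness: float = 4.0  # Gaussian kernel sigma, cells
    ph_clip: tuple[float, float] = (3.8, 9.0)
    sand_mean: float = 45.0
    sand_sd: float = 22.0
    clay_mean: float = 25.0
    clay_sd: float = 14.0
    texture_smoothness: float = 4.0
    n_low_fraction: float = 0.4
    n_low_mean: float = 12.0
    n_high_mean: float = 120.0
    yield_median: float = 3.0  # t/ha
    yield_sigma: float = 0.5
    area_median: float = 500.0  # ha per cell
    area_sigma: float = 1.0
    zero_area_fraction: float = 0.1
    n_regions: int = 8
    missing_fraction: float = 0.1  # abundance cells without data

    def __post_init__(self) -> None:
        for frac in (self.missing_fraction, self.n_low_fraction,
                     self.zero_area_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if min(self.shape) < 1:
            raise ValueError("shape must be positive")
        if not 1 <= self.n_regions <= len(DEFAULT_REGION_NAMES):
            raise ValueError(
                f"n_regions must be in 1..{len(DEFAULT_REGION_NAMES)}")

    @property
    def transform(self) -> GridTransform:
        return GridTransform(cell_arcmin=self.cell_arcmin)


@dataclass
class World:
    """A complete set of synthetic input layers on one geometry."""

    abundance: Grid
    ph_stack: list[Grid]
    sand: Grid
    clay: Grid
    crops: list[CropLayer]
    regions: RegionMap
    config: WorldConfig

    @property
    def crop_groups(self) -> dict[str, str]:
        return {c.crop: ("cereal" if c.crop_type == "cereal_grains" else "legume")
                for c in self.crops}

    def ph(self) -> Grid:
        return depth_weighted_average(self.ph_stack)

    def ph_categories(self) -> CategoryGrid:
        return classify_ph(self.ph())

    def texture_categories(self) -> CategoryGrid:
        return classify_texture(self.sand, self.clay)


def _smooth_field(rng: np.random.Generator, shape, mean, sd, sigma) -> np.ndarray:
    """Spatially correlated Gaussian field with the requested mean and sd."""
    noise = rng.standard_normal(shape)
    if sigma > 0:
        noise = ndimage.gaussian_filter(noise, sigma=sigma, mode="wrap")
        s = noise.std()
        if s > 0:
            noise = noise / s
    return mean + sd * noise


def generate_world(config: WorldConfig | None = None) -> World:
    """Draw a fully reproducible synthetic world from the config's seed."""
    cfg = config or WorldConfig()
    rng = np.random.default_rng(cfg.seed)
    shape, t = cfg.shape, cfg.transform

    abundance_vals = rng.lognormal(cfg.abundance_mu, cfg.abundance_sigma, shape)
    miss = rng.random(shape) < cfg.missing_fraction
    abundance = Grid(values=np.where(miss, np.nan, abundance_vals),
                     transform=t, mask=miss)

    lo, hi = cfg.ph_clip
    ph_stack = []
    for _ in range(5):
        layer = _smooth_field(rng, shape, cfg.ph_mean, cfg.ph_sd,
                              cfg.ph_smoothness)
        ph_stack.append(Grid(values=np.clip(layer, lo, hi), transform=t))

    sand = np.clip(_smooth_field(rng, shape, cfg.sand_mean, cfg.sand_sd,
                                 cfg.texture_smoothness), 0, 95)
    clay = np.clip(_smooth_field(rng, shape, cfg.clay_mean, cfg.clay_sd,
                                 cfg.texture_smoothness), 0, 95)
    # keep the composition physical: rescale where sand + clay > 95
    total = sand + clay
    over = total > 95
    scale = np.where(over, 95.0 / np.where(over, total, 1.0), 1.0)
    sand_g = Grid(values=sand * scale, transform=t)
    clay_g = Grid(values=clay * scale, transform=t)

    crops = []
    for name, crop_type in cfg.crops:
        y = rng.lognormal(np.log(cfg.yield_median), cfg.yield_sigma, shape)
        area = rng.lognormal(np.log(cfg.area_median), cfg.area_sigma, shape)
        area[rng.random(shape) < cfg.zero_area_fraction] = 0.0
        low = rng.random(shape) < cfg.n_low_fraction
        n_rate = np.where(
            low,
            rng.gamma(4.0, cfg.n_low_mean / 4.0, shape),
            rng.gamma(6.0, cfg.n_high_mean / 6.0, shape),
        )
        crops.append(CropLayer(
            crop=name, crop_type=crop_type,
            yield_grid=Grid(values=y, transform=t),
            area=Grid(values=area, transform=t),
            n_rate=Grid(values=np.clip(n_rate, 0, None), transform=t),
        ))

    regions = _block_regions(shape, cfg.n_regions, t)
    return World(abundance=abundance, ph_stack=ph_stack, sand=sand_g,
                 clay=clay_g, crops=crops, regions=regions, config=cfg)


def _block_regions(shape, n_regions: int, transform: GridTransform) -> RegionMap:
    """Partition the grid into contiguous column bands, one per region."""
    nrows, ncols = shape
    cols = np.arange(ncols)
    band = np.minimum((cols * n_regions) // ncols, n_regions - 1)
    codes = np.broadcast_to(band, (nrows, ncols)).astype(np.int16).copy()
    names = {i: DEFAULT_REGION_NAMES[i] for i in range(n_regions)}
    cat = CategoryGrid(codes=codes, labels=tuple(names[i] for i in range(n_regions)),
                       factor="region", transform=transform)
    return RegionMap(regions=cat, names=names)


@dataclass
class TruthWorld:
    """A world whose observed yields were constructed from known truth."""

    world: World
    effects: dict[str, Grid]  # per-crop E
    baseline_yields: dict[str, Grid]  # without-earthworm yields
    truth_regional: pd.DataFrame  # exact attributable production


def generate_with_truth(config: WorldConfig | None = None,
                        params: EffectParams | None = None) -> TruthWorld:
    """Generate a world whose observed yields embed a known earthworm effect.

    Drawn yields are reinterpreted as baseline (earthworm-free) yields; the
    effect model is evaluated on the generated drivers, observed yields are
    set to baseline * (1 + E), and the exact attributable production
    baseline * E * area is summed per region and crop group.  Running the
    pipeline in counterfactual-division mode on the observed yields must
    recover this table.
    """
    from .aggregate import regional_summary

    world = generate_world(config)
    if params is None:
        params = EffectParams.from_effect_table()
    ph_cat = world.ph_categories()
    tex_cat = world.texture_categories()

    effects: dict[str, Grid] = {}
    baselines: dict[str, Grid] = {}
    contributions: dict[str, Grid] = {}
    observed_production: dict[str, Grid] = {}
    for crop in world.crops:
        eg = earthworm_effect(crop, ph_cat, tex_cat, world.abundance, params)
        baseline = crop.yield_grid
        with np.errstate(invalid="ignore"):
            obs_vals = baseline.values * (1.0 + eg.E.values)
            contrib_vals = baseline.values * eg.E.values * crop.area.values
            obs_prod_vals = obs_vals * crop.area.values
        mask = eg.E.mask | baseline.mask | crop.area.mask
        # overwrite the crop's yield grid with the constructed observed yield
        crop.yield_grid = Grid(values=np.where(eg.E.mask, np.nan, obs_vals),
                               transform=baseline.transform, mask=eg.E.mask)
        effects[crop.crop] = eg.E
        baselines[crop.crop] = baseline
        contributions[crop.crop] = Grid(values=np.where(mask, np.nan, contrib_vals),
                                        transform=baseline.transform, mask=mask)
        observed_production[crop.crop] = Grid(
            values=np.where(mask, np.nan, obs_prod_vals),
            transform=baseline.transform, mask=mask)

    truth = regional_summary(contributions, observed_production,
                             world.regions, world.crop_groups)
    return TruthWorld(world=world, effects=effects, baseline_yields=baselines,
                      truth_regional=truth)
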