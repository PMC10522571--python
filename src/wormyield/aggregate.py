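"""Cross-crop area weighting and regional/global production summaries.

Relative contributions are reported against OBSERVED (with-earthworm)
production; cells without earthworm data are excluded from both numerator
and denominator by default, since they never enter the effect model.  The
``include_all_production`` switch puts all observed production in the
denominator instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .layers import CategoryGrid, Grid, align_check

logger = logging.getLogger(__name__)

#: Eight continental-scale agricultural regions (UN SDG groupings with
#: Australia/New Zealand folded into Oceania, Europe and Northern America
#: kept separate).
DEFAULT_REGION_NAMES = (
    "Sub-Saharan Africa",
    "Northern Africa and Western Asia",
    "Central and Southern Asia",
    "Eastern and South-Eastern Asia",
    "Latin America and the Caribbean",
    "Oceania",
    "Europe",
    "Northern America",
)

CROP_GROUPS = ("cereal", "legume", "all")
GLOBAL_LABEL = "Global"
UNASSIGNED_LABEL = "unassigned"


@dataclass
class RegionMap:
    """Region-identifier raster plus identifier -> name mapping."""

    regions: CategoryGrid
    names: Mapping[int, str]

    def __post_init__(self) -> None:
        valid = self.regions.codes[~self.regions.mask]
        unknown = set(np.unique(valid)) - set(self.names)
        if unknown:
            raise ValueError(f"region codes without names: {sorted(unknown)}")


def area_weighted_effect(effects: Sequence["EffectGrid"],
                         areas: Sequence[Grid]) -> Grid:
    """Harvested-area-weighted mean effect across crops, per cell.

    Crops contribute where their effect is unmasked and their area positive;
    cells with no contributing crop become missing.
    """
    from .effect import EffectGrid  # local import to avoid a cycle

    if len(effects) != len(areas):
        raise ValueError("one area grid per effect grid required")
    if not effects:
        raise ValueError("no effect grids")
    align_check([e.E for e in effects] + list(areas))
    num = np.zeros(effects[0].E.shape)
    den = np.zeros_like(num)
    for eg, ar in zip(effects, areas):
        ok = eg.E.valid() & ar.valid() & (ar.values > 0)
        num[ok] += ar.values[ok] * eg.E.values[ok]
        den[ok] += ar.values[ok]
    mask = den == 0
    out = np.where(mask, np.nan, num / np.where(mask, 1.0, den))
    return Grid(values=out, transform=effects[0].E.transform, mask=mask)


def _group_of(crop: str, groups: Mapping[str, str]) -> str:
    try:
        return groups[crop]
    except KeyError:
        raise KeyError(f"crop {crop!r} has no group assignment") from None


def regional_summary(
    contributions: Mapping[str, Grid],
    observed: Mapping[str, Grid],
    regions: RegionMap,
    groups: Mapping[str, str],
    include_all_production: bool = False,
) -> pd.DataFrame:
    """Per-region, per-crop-group production totals and earthworm shares.

    Returns rows (region, crop_group) with observed production, counterfactual
    production, absolute contribution (t) and relative contribution (% of
    observed).  A Global row per group sums the regional rows.  Production in
    cells with no region assignment is tallied under ``unassigned``.
    """
    if set(contributions) != set(observed):
        raise ValueError("contribution and observed crop sets differ")
    grids = list(contributions.values()) + list(observed.values())
    align_check(grids + [regions.regions])
    codes = regions.regions.codes
    rmask = regions.regions.mask

    region_ids = sorted(regions.names)
    rows = []
    # accumulate sums: region x group
    acc: dict[tuple[str, str], dict[str, float]] = {}

    def _add(region: str, group: str, contrib: float, obs: float) -> None:
        for g in (group, "all"):
            cell = acc.setdefault((region, g), {"contribution_t": 0.0,
                                                "observed_t": 0.0})
            cell["contribution_t"] += contrib
            cell["observed_t"] += obs

    for crop, contrib in contributions.items():
        group = _group_of(crop, groups)
        obs = observed[crop]
        valid_c = contrib.valid()
        if include_all_production:
            valid_o = obs.valid()
        else:
            valid_o = valid_c & obs.valid()
        for rid in region_ids:
            sel = (codes == rid) & ~rmask
            _add(regions.names[rid], group,
                 float(np.sum(contrib.values[sel & valid_c])),
                 float(np.sum(obs.values[sel & valid_o])))
        orphan = rmask & (valid_c | valid_o)
        if np.any(orphan):
            n_orphan = int(np.sum(orphan))
            logger.warning("%d cells with production but no region for crop %s",
                           n_orphan, crop)
            _add(UNASSIGNED_LABEL, group,
                 float(np.sum(contrib.values[orphan & valid_c])),
                 float(np.sum(obs.values[orphan & valid_o])))

    region_order = [regions.names[r] for r in region_ids]
    if any(r == UNASSIGNED_LABEL for r, _ in acc):
        region_order.append(UNASSIGNED_LABEL)
    for region in region_order:
        for g in CROP_GROUPS:
            cell = acc.get((region, g), {"contribution_t": 0.0, "observed_t": 0.0})
            rows.append(_summary_row(region, g, cell))
    # global rows: exact sums of the same summands
    for g in CROP_GROUPS:
        cell = {"contribution_t": sum(acc.get((r, g), {}).get("contribution_t", 0.0)
                                      for r in region_order),
                "observed_t": sum(acc.get((r, g), {}).get("observed_t", 0.0)
                                  for r in region_order)}
        rows.append(_summary_row(GLOBAL_LABEL, g, cell))
    return pd.DataFrame.from_records(rows)


def _summary_row(region: str, group: str, cell: Mapping[str, float]) -> dict:
    obs = cell["observed_t"]
    contrib = cell["contribution_t"]
    pct = 100.0 * contrib / obs if obs > 0 else np.nan
    return {
        "region": region,
        "crop_group": group,
        "observed_t": obs,
        "counterfactual_t": obs - contrib,
        "contribution_t": contrib,
        "contribution_pct": pct,
    }


def global_summary(
    contributions: Mapping[str, Grid],
    observed: Mapping[str, Grid],
    groups: Mapping[str, str],
    include_all_production: bool = False,
) -> pd.DataFrame:
    """Regional summary collapsed to a single region covering every cell."""
    any_grid = next(iter(contributions.values()))
    codes = np.zeros(any_grid.shape, dtype=np.int16)
    world = RegionMap(
        regions=CategoryGrid(codes=codes, labels=(GLOBAL_LABEL,),
                             factor="region", transform=any_grid.transform),
        names={0: GLOBAL_LABEL},
    )
    df = regional_summary(contributions, observed, world, groups,
                          include_all_production=include_all_production)
    df = df[df["region"] == GLOBAL_LABEL]
    return df.drop_duplicates(subset=["crop_group"]).reset_index(drop=True)
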