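"""Per-cell earthworm effect and counterfactual yield attribution.

The fractional yield effect in cell i for crop k is the product

    E_ik = c_k * p_i * t_i * n_ik * a_i * E0

where c, p, t, n are the multiplicative coefficients for the cell's crop
type, soil-pH class, texture class and crop-specific N-rate class, a is the
continuous abundance multiplier, and E0 is the baseline fractional biomass
response to earthworm presence (default 0.233, i.e. a 23.3% average
increase).  Factors are treated as independent multipliers; no interaction
terms are modeled.

Two conventions convert E into a without-earthworm yield:

``counterfactual_division`` (default)
    Observed yields already include earthworms: y_without = y_obs / (1 + E),
    so the attributable share of observed production is E / (1 + E).
``forward_multiplication``
    Observed yields are earthworm-free: y_with = y_obs * (1 + E).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .coefficients import (
    AbundancePowerParams,
    FactorCoefficients,
    abundance_multiplier,
    derive_all_coefficients,
    load_effect_table,
)
from .layers import CategoryGrid, CropLayer, Grid, align_check, classify_n_rate

logger = logging.getLogger(__name__)

#: Mean fractional increase in aboveground biomass with earthworms present.
DEFAULT_BASELINE_EFFECT = 0.233

MODES = ("counterfactual_division", "forward_multiplication")


@dataclass(frozen=True)
class EffectParams:
    """Full parameterization of the per-cell effect model."""

    crop_coefs: FactorCoefficients
    ph_coefs: FactorCoefficients
    texture_coefs: FactorCoefficients
    n_coefs: FactorCoefficients
    abundance_params: AbundancePowerParams = field(
        default_factory=AbundancePowerParams
    )
    baseline_effect: float = DEFAULT_BASELINE_EFFECT
    contribution_mode: str = "counterfactual_division"

    def __post_init__(self) -> None:
        if self.baseline_effect <= 0:
            raise ValueError("baseline effect must be positive")
        if self.contribution_mode not in MODES:
            raise ValueError(f"unknown contribution mode {self.contribution_mode!r}")

    @classmethod
    def from_effect_table(cls, path=None, **kwargs) -> "EffectParams":
        """Build params from an effect-size CSV (default: shipped table)."""
        coefs = derive_all_coefficients(load_effect_table(path))
        return cls(
            crop_coefs=coefs["crop_type"],
            ph_coefs=coefs["soil_ph"],
            texture_coefs=coefs["soil_texture"],
            n_coefs=coefs["n_rate"],
            **kwargs,
        )


@dataclass
class EffectGrid:
    """Dimensionless fractional yield effect for one crop."""

    crop: str
    E: Grid


def earthworm_effect(
    crop: CropLayer,
    ph_cat: CategoryGrid,
    tex_cat: CategoryGrid,
    abundance: Grid,
    params: EffectParams,
) -> EffectGrid:
    """Evaluate the multiplicative effect model for one crop on the full grid.

    Cells missing any driver — notably cells without earthworm abundance
    data — are masked, never defaulted.  The N-rate class is derived from the
    crop's own fertilization layer, so n varies by crop as well as by cell.
    """
    align_check([crop.yield_grid, ph_cat, tex_cat, abundance, crop.n_rate])
    c = params.crop_coefs[crop.crop_type]
    n_cat = classify_n_rate(crop.n_rate)
    p = ph_cat.coefficient_field(params.ph_coefs.coefficients)
    t = tex_cat.coefficient_field(params.texture_coefs.coefficients)
    n = n_cat.coefficient_field(params.n_coefs.coefficients)
    mask = (
        ph_cat.mask | tex_cat.mask | n_cat.mask | abundance.mask
        | crop.yield_grid.mask
    )
    a = np.zeros(abundance.shape)
    ok = ~abundance.mask
    a[ok] = abundance_multiplier(abundance.values[ok], params.abundance_params)
    with np.errstate(invalid="ignore"):
        E = c * p * t * n * a * params.baseline_effect
    if np.any(E[~mask & ~np.isnan(E)] < 0):
        logger.warning("negative effect values clamped to 0 "
                       "(user-supplied negative coefficients?)")
        E = np.clip(E, 0.0, None)
    E = np.where(mask, np.nan, E)
    return EffectGrid(crop=crop.crop,
                      E=Grid(values=E, transform=abundance.transform, mask=mask))


def counterfactual_yield(y_obs: Grid, effect: EffectGrid,
                         mode: str = "counterfactual_division") -> Grid:
    """Yield the cell would produce without earthworms, under either convention."""
    if mode not in MODES:
        raise ValueError(f"unknown contribution mode {mode!r}")
    align_check([y_obs, effect.E])
    mask = y_obs.mask | effect.E.mask
    with np.errstate(invalid="ignore"):
        if mode == "counterfactual_division":
            y_without = y_obs.values / (1.0 + effect.E.values)
        else:
            y_without = y_obs.values.copy()
    y_without = np.where(mask, np.nan, y_without)
    return Grid(values=y_without, transform=y_obs.transform, mask=mask)


def with_earthworm_yield(y_obs: Grid, effect: EffectGrid, mode: str) -> Grid:
    """The with-earthworm yield under the chosen convention."""
    if mode == "counterfactual_division":
        return Grid(values=y_obs.values.copy(), transform=y_obs.transform,
                    mask=(y_obs.mask | effect.E.mask))
    align_check([y_obs, effect.E])
    mask = y_obs.mask | effect.E.mask
    with np.errstate(invalid="ignore"):
        y_with = y_obs.values * (1.0 + effect.E.values)
    return Grid(values=np.where(mask, np.nan, y_with),
                transform=y_obs.transform, mask=mask)


def production_contribution(y_with: Grid, y_without: Grid, area: Grid) -> Grid:
    """Attributable production per cell: (y_with - y_without) * area, tonnes."""
    align_check([y_with, y_without, area])
    mask = y_with.mask | y_without.mask | area.mask
    with np.errstate(invalid="ignore"):
        contrib = (y_with.values - y_without.values) * area.values
    contrib = np.where(mask, np.nan, contrib)
    return Grid(values=contrib, transform=area.transform, mask=mask)
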