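"""Multiplicative effect coefficients from meta-analysis effect sizes.

The earthworm effect on aboveground biomass varies with crop type, soil pH,
soil texture and fertilizer N rate.  For each factor the meta-analysis reports
a percent effect per category together with the number of underlying data
points.  This module turns those rows into dimensionless multipliers: the
sample-size-weighted mean effect of a factor is the reference level, and each
category's coefficient is its effect divided by that reference, so that the
weighted mean of the coefficients is 1 by construction.

Earthworm abundance enters continuously instead, as a power law
``multiplier = k * abundance**b`` through the origin, so that sparsely
populated soils receive a near-zero effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

FACTORS = ("crop_type", "soil_ph", "soil_texture", "n_rate")

#: Default abundance power-law parameters shipped with the package.
DEFAULT_ABUNDANCE_PREFACTOR = 0.1032
DEFAULT_ABUNDANCE_EXPONENT = 0.409


@dataclass(frozen=True)
class EffectCategory:
    """One category of one factor: its sample size and percent effect."""

    factor: str
    category: str
    sample_size: int
    effect_percent: float
    applies_to_map: bool = True

    def __post_init__(self) -> None:
        if self.factor not in FACTORS:
            raise ValueError(f"unknown factor {self.factor!r}")
        if self.sample_size <= 0:
            raise ValueError("sample_size must be positive")


@dataclass(frozen=True)
class FactorCoefficients:
    """Per-category multipliers for one factor, relative to its weighted mean."""

    factor: str
    weighted_mean_effect_percent: float
    coefficients: Mapping[str, float]

    def __getitem__(self, category: str) -> float:
        try:
            return self.coefficients[category]
        except KeyError:
            raise KeyError(
                f"no coefficient for category {category!r} of factor {self.factor!r}"
            ) from None


@dataclass(frozen=True)
class AbundancePowerParams:
    """Parameters of the continuous abundance multiplier k * x**b."""

    prefactor: float = DEFAULT_ABUNDANCE_PREFACTOR
    exponent: float = DEFAULT_ABUNDANCE_EXPONENT

    def __post_init__(self) -> None:
        if self.prefactor <= 0 or self.exponent <= 0:
            raise ValueError("prefactor and exponent must be positive")


def weighted_mean_effect(categories: Sequence[EffectCategory]) -> float:
    """Sample-size-weighted mean percent effect across a factor's categories.

    All categories contribute, including ones that never map onto a data
    layer (grasses): the reference level of a factor is defined by the full
    evidence base, not by the mappable subset.
    """
    if not categories:
        raise ValueError("need at least one category")
    factors = {c.factor for c in categories}
    if len(factors) != 1:
        raise ValueError(f"categories mix factors: {sorted(factors)}")
    n = np.array([c.sample_size for c in categories], dtype=float)
    e = np.array([c.effect_percent for c in categories], dtype=float)
    return float(np.sum(n * e) / np.sum(n))


def derive_coefficients(categories: Sequence[EffectCategory]) -> FactorCoefficients:
    """Coefficient for category j is e_j / mean, using the unrounded weighted mean.

    Categories flagged ``applies_to_map=False`` still shape the mean but get
    no coefficient (there is no map layer to apply one to).
    """
    mean = weighted_mean_effect(categories)
    if mean == 0:
        raise ValueError("weighted mean effect is zero; coefficients undefined")
    labels = [c.category for c in categories]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate category labels within factor")
    coefs = {
        c.category: c.effect_percent / mean for c in categories if c.applies_to_map
    }
    return FactorCoefficients(
        factor=categories[0].factor,
        weighted_mean_effect_percent=mean,
        coefficients=coefs,
    )


def abundance_multiplier(abundance, params: AbundancePowerParams | None = None):
    """Continuous earthworm-abundance multiplier k * abundance**b.

    Accepts scalars or arrays; zero abundance yields exactly zero.
    """
    if params is None:
        params = AbundancePowerParams()
    a = np.asarray(abundance, dtype=float)
    if np.any(a < 0):
        raise ValueError("abundance must be nonnegative")
    out = params.prefactor * np.power(a, params.exponent)
    if np.ndim(abundance) == 0:
        return float(out)
    return out


def fit_abundance_power(
    points: Iterable[tuple[float, float]],
) -> AbundancePowerParams:
    """Least-squares fit of k * x**b via OLS on log-log transformed points.

    Exact on noiseless power-law samples; requires at least two points with
    strictly positive abundance and multiplier.
    """
    pts = list(points)
    if len(pts) < 2:
        raise ValueError("need at least two points to fit a power law")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires positive abundances and multipliers")
    b, logk = np.polyfit(np.log(x), np.log(y), 1)
    # b may round to exactly 0 on constant data; params require positivity only
    # for the shipped defaults, so relax here by bypassing validation.
    params = object.__new__(AbundancePowerParams)
    object.__setattr__(params, "prefactor", float(math.exp(logk)))
    object.__setattr__(params, "exponent", float(b))
    return params


# ---------------------------------------------------------------------------
# Table I/O


def load_effect_table(path: str | Path | None = None) -> list[EffectCategory]:
    """Read an effect-size table (CSV); defaults to the shipped transcription."""
    if path is None:
        with resources.as_file(
            resources.files("wormyield.data").joinpath("effect_sizes.csv")
        ) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"factor", "category", "sample_size", "effect_percent"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"effect table missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("effect table is empty")
    if "applies_to_map" not in df.columns:
        df["applies_to_map"] = True
    rows = []
    for rec in df.itertuples(index=False):
        applies = rec.applies_to_map
        if isinstance(applies, str):
            applies = applies.strip().lower() in {"true", "1", "yes"}
        rows.append(
            EffectCategory(
                factor=str(rec.factor),
                category=str(rec.category),
                sample_size=int(rec.sample_size),
                effect_percent=float(rec.effect_percent),
                applies_to_map=bool(applies),
            )
        )
    return rows


def derive_all_coefficients(
    categories: Sequence[EffectCategory],
) -> dict[str, FactorCoefficients]:
    """Group an effect table by factor and derive coefficients for each."""
    out: dict[str, FactorCoefficients] = {}
    for factor in FACTORS:
        rows = [c for c in categories if c.factor == factor]
        if rows:
            out[factor] = derive_coefficients(rows)
    return out


def coefficients_frame(coefs: Mapping[str, FactorCoefficients]) -> pd.DataFrame:
    """Flatten derived coefficients to a table for CSV export."""
    records = [
        {
            "factor": fc.factor,
            "category": cat,
            "coefficient": val,
            "weighted_mean_effect_percent": fc.weighted_mean_effect_percent,
        }
        for fc in coefs.values()
        for cat, val in fc.coefficients.items()
    ]
    return pd.DataFrame.from_records(
        records,
        columns=["factor", "category", "coefficient", "weighted_mean_effect_percent"],
    )
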