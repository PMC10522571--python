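"""Per-cell effect model, counterfactual yields, attributable production."""

import numpy as np
import pytest

from wormyield import (
    AbundancePowerParams,
    CategoryGrid,
    CropLayer,
    EffectParams,
    FactorCoefficients,
    Grid,
    abundance_multiplier,
    counterfactual_yield,
    earthworm_effect,
    production_contribution,
)
from wormyield.effect import EffectGrid, with_earthworm_yield
from wormyield.layers import (
    N_RATE_CATEGORIES,
    PH_CATEGORIES,
    TEXTURE_CATEGORIES,
)

from conftest import make_grid


def _unit_params(**overrides):
    """Params with every categorical coefficient equal to 1."""
    kwargs = dict(
        crop_coefs=FactorCoefficients("crop_type", 1.0,
                                      {"cereal_grains": 1.0, "legumes": 1.0}),
        ph_coefs=FactorCoefficients("soil_ph", 1.0,
                                    {c: 1.0 for c in PH_CATEGORIES}),
        texture_coefs=FactorCoefficients("soil_texture", 1.0,
                                         {c: 1.0 for c in TEXTURE_CATEGORIES}),
        n_coefs=FactorCoefficients("n_rate", 1.0,
                                   {c: 1.0 for c in N_RATE_CATEGORIES}),
    )
    kwargs.update(overrides)
    return EffectParams(**kwargs)


def _world(shape=(3, 3), abundance=100.0, abundance_mask=None, n_rate=10.0):
    ph_cat = CategoryGrid(codes=np.zeros(shape, dtype=int),
                          labels=PH_CATEGORIES, factor="soil_ph")
    tex_cat = CategoryGrid(codes=np.zeros(shape, dtype=int),
                           labels=TEXTURE_CATEGORIES, factor="soil_texture")
    crop = CropLayer(
        crop="wheat", crop_type="cereal_grains",
        yield_grid=make_grid(np.full(shape, 5.0)),
        area=make_grid(np.full(shape, 100.0)),
        n_rate=make_grid(np.full(shape, float(n_rate))),
    )
    ab = make_grid(np.full(shape, float(abundance)), mask=abundance_mask)
    return crop, ph_cat, tex_cat, ab


def test_baseline_effect_with_unit_factors():
    """With all coefficients 1 and abundance multiplier 1, E is 0.233."""
    crop, ph, tex, ab = _world(abundance=(1 / 0.1032) ** (1 / 0.409))
    eg = earthworm_effect(crop, ph, tex, ab, _unit_params())
    assert np.allclose(eg.E.values, 0.233)


def test_zero_abundance_annihilates_effect():
    crop, ph, tex, ab = _world(abundance=0.0)
    eg = earthworm_effect(crop, ph, tex, ab, _unit_params())
    assert np.all(eg.E.values == 0.0)


def test_hand_computed_cell(params):
    """c=1.271, p=1.235 (low pH), t=1.711 (clayey), n=1.071 (low N),
    abundance 100 -> E ~= 0.455."""
    shape = (2, 2)
    ph = CategoryGrid(codes=np.zeros(shape, dtype=int), labels=PH_CATEGORIES,
                      factor="soil_ph")
    tex = CategoryGrid(codes=np.full(shape, 2, dtype=int),
                       labels=TEXTURE_CATEGORIES, factor="soil_texture")
    crop, _, _, ab = _world(shape, abundance=100.0, n_rate=10.0)
    eg = earthworm_effect(crop, ph, tex, ab, params)
    expected = (params.crop_coefs["cereal_grains"] * params.ph_coefs["low"]
                * params.texture_coefs["clayey"] * params.n_coefs["low"]
                * abundance_multiplier(100.0) * params.baseline_effect)
    assert np.allclose(eg.E.values, expected)
    # product of the printed rounded coefficients, hand-computed
    assert expected == pytest.approx(0.455, abs=0.002)


def test_missing_abundance_masks_effect(params):
    mask = np.zeros((3, 3), bool)
    mask[1, 1] = True
    crop, ph, tex, ab = _world(abundance_mask=mask)
    eg = earthworm_effect(crop, ph, tex, ab, params)
    assert eg.E.mask[1, 1]
    assert not eg.E.mask[0, 0]


def test_unknown_crop_type_rejected(params):
    crop, ph, tex, ab = _world()
    crop.crop_type = "tubers"
    with pytest.raises(KeyError):
        earthworm_effect(crop, ph, tex, ab, params)


def test_vectorized_matches_scalar_oracle(params):
    """Vectorized evaluation equals a per-cell scalar loop to 1e-12."""
    rng = np.random.default_rng(17)
    shape = (50, 50)
    ph = CategoryGrid(codes=rng.integers(0, 3, shape), labels=PH_CATEGORIES,
                      factor="soil_ph")
    tex = CategoryGrid(codes=rng.integers(0, 3, shape),
                       labels=TEXTURE_CATEGORIES, factor="soil_texture")
    n_rate_vals = rng.uniform(0, 200, shape)
    ab_vals = rng.lognormal(3.0, 1.0, shape)
    crop = CropLayer(
        crop="rice", crop_type="cereal_grains",
        yield_grid=make_grid(rng.uniform(0.5, 8, shape)),
        area=make_grid(rng.uniform(0, 1000, shape)),
        n_rate=make_grid(n_rate_vals),
    )
    eg = earthworm_effect(crop, ph, tex, make_grid(ab_vals), params)

    c = params.crop_coefs["cereal_grains"]
    k, b = params.abundance_params.prefactor, params.abundance_params.exponent
    for i in range(shape[0]):
        for j in range(shape[1]):
            p = params.ph_coefs[PH_CATEGORIES[ph.codes[i, j]]]
            t = params.texture_coefs[TEXTURE_CATEGORIES[tex.codes[i, j]]]
            n = params.n_coefs["low" if n_rate_vals[i, j] <= 30 else "high"]
            a = k * ab_vals[i, j] ** b
            expected = c * p * t * n * a * 0.233
            assert eg.E.values[i, j] == pytest.approx(expected, abs=1e-12)


def test_effect_monotone_in_abundance(params):
    crop, ph, tex, ab_lo = _world(abundance=50.0)
    _, _, _, ab_hi = _world(abundance=80.0)
    e_lo = earthworm_effect(crop, ph, tex, ab_lo, params).E.values
    e_hi = earthworm_effect(crop, ph, tex, ab_hi, params).E.values
    assert np.all(e_hi >= e_lo)


def test_larger_coefficient_never_decreases_effect(params):
    """Swapping low pH (1.235) for medium (1.242) raises E."""
    crop, _, tex, ab = _world()
    low = CategoryGrid(codes=np.zeros((3, 3), dtype=int), labels=PH_CATEGORIES,
                       factor="soil_ph")
    med = CategoryGrid(codes=np.ones((3, 3), dtype=int), labels=PH_CATEGORIES,
                       factor="soil_ph")
    e_low = earthworm_effect(crop, low, tex, ab, params).E.values
    e_med = earthworm_effect(crop, med, tex, ab, params).E.values
    assert np.all(e_med >= e_low)


def test_negative_coefficients_clamped_to_zero():
    params = _unit_params(
        crop_coefs=FactorCoefficients("crop_type", 1.0,
                                      {"cereal_grains": -0.5, "legumes": 1.0}))
    crop, ph, tex, ab = _world()
    eg = earthworm_effect(crop, ph, tex, ab, params)
    assert np.all(eg.E.values[~eg.E.mask] == 0.0)


class TestCounterfactual:
    def _effect(self, E, shape=(2, 2), mask=None):
        return EffectGrid(crop="wheat",
                          E=make_grid(np.full(shape, float(E)), mask=mask))

    def test_division_mode(self):
        y = make_grid(np.full((2, 2), 5.0))
        out = counterfactual_yield(y, self._effect(0.25))
        assert np.allclose(out.values, 4.0)

    def test_zero_effect_is_identity(self):
        y = make_grid(np.full((2, 2), 5.0))
        out = counterfactual_yield(y, self._effect(0.0))
        assert np.allclose(out.values, 5.0)

    def test_relative_contribution_is_e_over_one_plus_e(self):
        y = make_grid(np.full((2, 2), 5.0))
        eg = self._effect(1.0)
        y_wo = counterfactual_yield(y, eg)
        contribution = y.values - y_wo.values
        assert np.allclose(contribution, 2.5)
        assert np.allclose(contribution / y.values, 0.5)

    def test_forward_mode_keeps_observed_as_baseline(self):
        y = make_grid(np.full((2, 2), 5.0))
        eg = self._effect(0.2)
        y_wo = counterfactual_yield(y, eg, mode="forward_multiplication")
        y_with = with_earthworm_yield(y, eg, mode="forward_multiplication")
        assert np.allclose(y_wo.values, 5.0)
        assert np.allclose(y_with.values, 6.0)

    def test_unknown_mode_rejected(self):
        y = make_grid(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            counterfactual_yield(y, self._effect(0.1), mode="bogus")


class TestProductionContribution:
    def test_tonnage(self):
        y_with = make_grid(np.full((2, 2), 5.0))
        y_without = make_grid(np.full((2, 2), 4.0))
        area = make_grid(np.full((2, 2), 100.0))
        out = production_contribution(y_with, y_without, area)
        assert np.allclose(out.values, 100.0)

    def test_zero_area_gives_zero(self):
        y_with = make_grid(np.full((2, 2), 9.0))
        y_without = make_grid(np.full((2, 2), 1.0))
        area = make_grid(np.zeros((2, 2)))
        out = production_contribution(y_with, y_without, area)
        assert np.all(out.values == 0.0)

    def test_mask_propagates(self):
        mask = np.array([[True, False], [False, False]])
        y_with = make_grid(np.full((2, 2), 5.0), mask=mask)
        y_without = make_grid(np.full((2, 2), 4.0))
        area = make_grid(np.full((2, 2), 10.0))
        out = production_contribution(y_with, y_without, area)
        assert out.mask[0, 0] and not out.mask[0, 1]
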