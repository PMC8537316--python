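"""Report-shaped tables: matched-serve nutrients and footprints.

These produce the two standard comparison tables for a reference food and
its matched alternatives — a nutrient table (serve weight, nutrients,
estimated absorbed iron) and an environmental table (per-serve and
per-pregnancy footprints with the car-distance equivalent of each food's
pregnancy GHG total). Rounding conventions: nutrients 1 dp, absorbed
iron 2 dp, footprints 1 dp, water to whole litres at serve scale, km to
whole km, all half-up; underlying computation is unrounded.
"""
from __future__ import annotations

import pandas as pd

from ._rounding import round_half_up
from .bioavailability import DEFAULT_IRON_PARAMS, IronAbsorptionParams, absorbed_iron
from .foods import FoodTable
from .footprint import (
    DEFAULT_SCALING,
    DEFAULT_VEHICLE,
    PregnancyScaling,
    VehicleEquivalence,
    car_km_equivalent,
    pregnancy_footprint,
    serve_footprint,
)
from .matching import MatchBasis, match_serve, standard_serve

__all__ = ["matched_serve_table", "footprint_table"]


def _serves(table: FoodTable, reference: str, basis: MatchBasis | str):
    ref = table[reference]
    basis = MatchBasis(basis)
    yield standard_serve(ref)
    for food in table:
        if food.name != reference:
            yield match_serve(food, ref, basis)


def matched_serve_table(
    table: FoodTable,
    reference: str,
    basis: MatchBasis | str = MatchBasis.ENERGY,
    params: IronAbsorptionParams = DEFAULT_IRON_PARAMS,
) -> pd.DataFrame:
    """Nutrient comparison of the reference serve and matched alternatives."""
    rows = []
    for serve in _serves(table, reference, basis):
        p = serve.profile
        rows.append({
            "food": serve.food.name,
            "origin": serve.food.origin.value,
            "serve_g": round_half_up(serve.weight_cooked, 0),
            "energy_kj": round_half_up(p.energy, 0),
            "protein_g": round_half_up(p.protein, 1),
            "sfa_g": round_half_up(p.saturated_fat, 1),
            "fiber_g": round_half_up(p.dietary_fiber, 1),
            "iron_mg": round_half_up(p.iron, 1),
            "absorbed_iron_mg": round_half_up(
                absorbed_iron(p.iron, serve.food.origin, params), 2),
            "zinc_mg": round_half_up(p.zinc, 1),
            "calcium_mg": round_half_up(p.calcium, 1),
            "iodine_ug": round_half_up(p.iodine, 1),
            "folate_dfe_ug": round_half_up(p.folate_dfe, 1),
        })
    return pd.DataFrame(rows)


def footprint_table(
    table: FoodTable,
    reference: str,
    basis: MatchBasis | str = MatchBasis.ENERGY,
    scaling: PregnancyScaling = DEFAULT_SCALING,
    equiv: VehicleEquivalence = DEFAULT_VEHICLE,
) -> pd.DataFrame:
    """Per-serve and per-pregnancy footprints of reference and alternatives."""
    rows = []
    for serve in _serves(table, reference, basis):
        fp = serve_footprint(serve)
        preg = pregnancy_footprint(fp, scaling)
        rows.append({
            "food": serve.food.name,
            "serve_ghg_kgco2e": round_half_up(fp.ghg, 1),
            "serve_land_m2": round_half_up(fp.land, 1),
            "serve_acid_gso2e": round_half_up(fp.acidifying, 1),
            "serve_eutroph_gpo4e": round_half_up(fp.eutrophying, 1),
            "serve_water_l": round_half_up(fp.water, 0),
            "pregnancy_ghg_kgco2e": round_half_up(preg.ghg, 1),
            "pregnancy_km_equiv": round_half_up(car_km_equivalent(preg.ghg, equiv), 0),
            "pregnancy_land_m2": round_half_up(preg.land, 1),
            "pregnancy_acid_gso2e": round_half_up(preg.acidifying, 1),
            "pregnancy_eutroph_gpo4e": round_half_up(preg.eutrophying, 1),
            "pregnancy_water_l": round_half_up(preg.water, 1),
        })
    return pd.DataFrame(rows)
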