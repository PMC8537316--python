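"""Net effect of swapping a reference food for a matched alternative.

A :class:`SwapScenario` names a reference food, an alternative, a matching
basis and a consumption pattern. Evaluating it composes the matching,
iron-bioavailability and footprint layers into a :class:`SwapResult`:
signed per-serve nutrient deltas (alternative minus reference), the
absorbed-iron delta, per-serve and per-pregnancy footprint deltas, and the
car-distance equivalent of any GHG reduction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from ._rounding import round_half_up
from .bioavailability import DEFAULT_IRON_PARAMS, IronAbsorptionParams, absorbed_iron
from .errors import ValidationError
from .foods import FoodTable, NutrientVector
from .footprint import (
    DEFAULT_SCALING,
    DEFAULT_VEHICLE,
    FootprintVector,
    PregnancyScaling,
    VehicleEquivalence,
    car_km_equivalent,
    pregnancy_footprint,
    serve_footprint,
)
from .matching import MatchBasis, MatchedServe, match_serve, standard_serve

logger = logging.getLogger(__name__)

__all__ = ["SwapScenario", "SwapResult", "evaluate_swap", "swap_report"]


@dataclass(frozen=True)
class SwapScenario:
    """Replace one serve of ``reference`` with a matched serve of ``alternative``."""

    reference: str
    alternative: str
    basis: MatchBasis = MatchBasis.ENERGY
    scaling: PregnancyScaling = field(default_factory=PregnancyScaling)

    def __post_init__(self) -> None:
        object.__setattr__(self, "basis", MatchBasis(self.basis))
        if self.reference == self.alternative:
            raise ValidationError(
                f"reference and alternative must differ (both {self.reference!r})"
            )


@dataclass(frozen=True)
class SwapResult:
    """All signed deltas are alternative minus reference."""

    scenario: SwapScenario
    reference_serve: MatchedServe
    alternative_serve: MatchedServe
    nutrient_delta: NutrientVector
    absorbed_iron_delta: float  # mg per serve
    footprint_delta_serve: FootprintVector
    footprint_delta_pregnancy: FootprintVector
    km_equivalent: float  # km of avoided driving; 0 unless GHG decreases


def evaluate_swap(
    table: FoodTable,
    scenario: SwapScenario,
    params: IronAbsorptionParams = DEFAULT_IRON_PARAMS,
    equiv: VehicleEquivalence = DEFAULT_VEHICLE,
) -> SwapResult:
    """Evaluate one swap scenario against a food table."""
    ref = table[scenario.reference]
    alt = table[scenario.alternative]
    ref_serve = standard_serve(ref)
    alt_serve = match_serve(alt, ref, scenario.basis)

    nutrient_delta = alt_serve.profile - ref_serve.profile
    iron_delta = (
        absorbed_iron(alt_serve.profile.iron, alt.origin, params)
        - absorbed_iron(ref_serve.profile.iron, ref.origin, params)
    )
    fp_serve = serve_footprint(alt_serve) - serve_footprint(ref_serve)
    fp_preg = pregnancy_footprint(fp_serve, scenario.scaling)

    if fp_preg.ghg < 0:
        km = car_km_equivalent(-fp_preg.ghg, equiv)
    else:
        km = 0.0
        if fp_preg.ghg > 0:
            logger.warning(
                "swap %s -> %s increases GHG emissions; km equivalent reported as 0",
                scenario.reference, scenario.alternative,
            )
    return SwapResult(
        scenario=scenario,
        reference_serve=ref_serve,
        alternative_serve=alt_serve,
        nutrient_delta=nutrient_delta,
        absorbed_iron_delta=iron_delta,
        footprint_delta_serve=fp_serve,
        footprint_delta_pregnancy=fp_preg,
        km_equivalent=km,
    )


def swap_report(
    table: FoodTable,
    scenarios: list[SwapScenario],
    params: IronAbsorptionParams = DEFAULT_IRON_PARAMS,
    equiv: VehicleEquivalence = DEFAULT_VEHICLE,
) -> pd.DataFrame:
    """One row per scenario, report-rounded, in input order.

    Nutrients round to 1 decimal, absorbed iron to 2, footprints to 1,
    km equivalents to whole km (all half-up).
    """
    rows = []
    for sc in scenarios:
        r = evaluate_swap(table, sc, params, equiv)
        nd = r.nutrient_delta
        row = {
            "reference": sc.reference,
            "alternative": sc.alternative,
            "basis": sc.basis.value,
            "frequency": sc.scaling.frequency.value,
            "alt_weight_cooked_g": round_half_up(r.alternative_serve.weight_cooked, 0),
            "d_energy_kj": round_half_up(nd.energy, 1),
            "d_protein_g": round_half_up(nd.protein, 1),
            "d_sfa_g": round_half_up(nd.saturated_fat, 1),
            "d_fiber_g": round_half_up(nd.dietary_fiber, 1),
            "d_iron_mg": round_half_up(nd.iron, 1),
            "d_absorbed_iron_mg": round_half_up(r.absorbed_iron_delta, 2),
            "d_zinc_mg": round_half_up(nd.zinc, 1),
            "d_calcium_mg": round_half_up(nd.calcium, 1),
            "d_iodine_ug": round_half_up(nd.iodine, 1),
            "d_folate_dfe_ug": round_half_up(nd.folate_dfe, 1),
        }
        for k, v in r.footprint_delta_serve.as_dict().items():
            row[f"d_serve_{k}"] = round_half_up(v, 1)
        for k, v in r.footprint_delta_pregnancy.as_dict().items():
            row[f"d_pregnancy_{k}"] = round_half_up(v, 1)
        row["km_equivalent"] = round_half_up(r.km_equivalent, 0)
        rows.append(row)
    return pd.DataFrame(rows)
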