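"""Portion matching: scale an alternative food to a reference serve.

A swap compares one standard serve of a reference food against a portion
of an alternative scaled to carry the same energy (isoenergetic) or the
same protein. The scale factor is applied to the alternative's own
standard serve, so all nutrients, the cooked weight and the retail weight
scale linearly together. Internals stay unrounded; the familiar
"94 g of firm tofu matches a 65 g beef serve" style of number appears
only when a report is printed.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .errors import ValidationError
from .foods import FoodItem, NutrientVector

__all__ = [
    "MatchBasis",
    "MatchedServe",
    "isoenergetic_serve",
    "protein_matched_serve",
    "standard_serve",
    "match_serve",
]


class MatchBasis(str, Enum):
    ENERGY = "energy"
    PROTEIN = "protein"
    FIXED = "fixed"  # the food's own standard serve, unscaled


@dataclass(frozen=True)
class MatchedServe:
    """A (possibly rescaled) serve of a food.

    ``scale`` is the ratio to the food's own standard serve; the nutrient
    profile and both serve weights are the standard-serve values times
    ``scale``.
    """

    food: FoodItem
    basis: MatchBasis
    scale: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValidationError(f"non-positive match scale for {self.food.name}")

    @property
    def profile(self) -> NutrientVector:
        return self.food.per_serve * self.scale

    @property
    def weight_cooked(self) -> float:
        """Cooked portion weight, g."""
        return self.food.serve_weight_cooked * self.scale

    @property
    def weight_retail(self) -> float:
        """Retail (purchasable) portion weight, kg."""
        return self.food.serve_weight_retail * self.scale


def isoenergetic_serve(alt: FoodItem, ref: FoodItem) -> MatchedServe:
    """Portion of ``alt`` with exactly the energy of one standard ``ref`` serve."""
    if alt.per_serve.energy <= 0:
        raise ValidationError(f"cannot energy-match zero-energy food {alt.name}")
    return MatchedServe(alt, MatchBasis.ENERGY,
                        ref.per_serve.energy / alt.per_serve.energy)


def protein_matched_serve(alt: FoodItem, ref: FoodItem) -> MatchedServe:
    """Portion of ``alt`` with exactly the protein of one standard ``ref`` serve."""
    if alt.per_serve.protein <= 0:
        raise ValidationError(f"cannot protein-match zero-protein food {alt.name}")
    return MatchedServe(alt, MatchBasis.PROTEIN,
                        ref.per_serve.protein / alt.per_serve.protein)


def standard_serve(food: FoodItem) -> MatchedServe:
    """The food's own standard serve (scale 1), for fixed-portion swaps."""
    return MatchedServe(food, MatchBasis.FIXED, 1.0)


def match_serve(alt: FoodItem, ref: FoodItem, basis: MatchBasis | str) -> MatchedServe:
    """Dispatch on the matching basis."""
    basis = MatchBasis(basis)
    if basis is MatchBasis.ENERGY:
        return isoenergetic_serve(alt, ref)
    if basis is MatchBasis.PROTEIN:
        return protein_matched_serve(alt, ref)
    return standard_serve(alt)
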