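"""Environmental footprints of serves and of sustained consumption.

The footprint of a serve is the food's per-kg environmental intensity
times the serve's retail weight. Sustained consumption over a pregnancy
(270 days by default) multiplies the per-serve footprint by the number of
serves: 270/7 ≈ 38.57 for a weekly habit, 270 for a daily one. GHG
totals can be translated into the distance an average passenger vehicle
would drive to emit the same mass of CO2-equivalents, using the US EPA
figure of 0.400 kg CO2 eq per mile.
"""
from __future__ import annotations

from dataclasses import dataclass, fields
from enum import Enum

from ._rounding import round_half_up
from .errors import ValidationError
from .matching import MatchedServe

__all__ = [
    "FootprintVector",
    "Frequency",
    "PregnancyScaling",
    "VehicleEquivalence",
    "DEFAULT_SCALING",
    "DEFAULT_VEHICLE",
    "serve_footprint",
    "pregnancy_footprint",
    "car_km_equivalent",
]


@dataclass(frozen=True)
class FootprintVector:
    """Environmental burden of some quantity of food.

    ghg in kg CO2 eq, land in m2, acidifying in g SO2 eq, eutrophying in
    g PO4(3-) eq, water (stress-weighted) in L. Single-food footprints are
    non-negative; differences between foods may be negative componentwise.
    """

    ghg: float = 0.0
    land: float = 0.0
    acidifying: float = 0.0
    eutrophying: float = 0.0
    water: float = 0.0

    def __add__(self, other: "FootprintVector") -> "FootprintVector":
        return FootprintVector(**{
            f.name: getattr(self, f.name) + getattr(other, f.name)
            for f in fields(self)
        })

    def __sub__(self, other: "FootprintVector") -> "FootprintVector":
        return self + (other * -1.0)

    def __mul__(self, factor: float) -> "FootprintVector":
        return FootprintVector(**{
            f.name: getattr(self, f.name) * factor for f in fields(self)
        })

    __rmul__ = __mul__

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


class Frequency(str, Enum):
    WEEKLY = "weekly"
    DAILY = "daily"


@dataclass(frozen=True)
class PregnancyScaling:
    """How often a serve is consumed, and for how long."""

    duration_days: float = 270.0
    frequency: Frequency = Frequency.WEEKLY

    def __post_init__(self) -> None:
        if self.duration_days < 0:
            raise ValidationError("duration_days must be >= 0")
        object.__setattr__(self, "frequency", Frequency(self.frequency))

    @property
    def n_serves(self) -> float:
        """Number of serves over the full duration (fractional for weekly)."""
        if self.frequency is Frequency.WEEKLY:
            return self.duration_days / 7.0
        return float(self.duration_days)


@dataclass(frozen=True)
class VehicleEquivalence:
    """Average-passenger-vehicle emission factor for GHG context-setting.

    0.400 kg CO2 eq per mile is the EPA typical-vehicle figure; the
    mile-to-km conversion is kept at 1.61, which is how published
    serve-to-distance figures in this literature are rounded.
    """

    kg_co2e_per_mile: float = 0.400
    km_per_mile: float = 1.61

    def __post_init__(self) -> None:
        if self.kg_co2e_per_mile <= 0 or self.km_per_mile <= 0:
            raise ValidationError("vehicle-equivalence factors must be positive")


DEFAULT_SCALING = PregnancyScaling()
DEFAULT_VEHICLE = VehicleEquivalence()


def serve_footprint(serve: MatchedServe) -> FootprintVector:
    """Footprint of one matched serve: per-kg intensity x retail weight."""
    w = serve.weight_retail
    i = serve.food.intensity
    return FootprintVector(
        ghg=i.ghg * w, land=i.land * w, acidifying=i.acidifying * w,
        eutrophying=i.eutrophying * w, water=i.water * w,
    )


def pregnancy_footprint(
    per_serve: FootprintVector, scaling: PregnancyScaling = DEFAULT_SCALING
) -> FootprintVector:
    """Total footprint of repeating a serve over the pregnancy."""
    return per_serve * scaling.n_serves


def car_km_equivalent(
    ghg: float, equiv: VehicleEquivalence = DEFAULT_VEHICLE, *, rounded: bool = True
) -> float:
    """Distance (km) an average car drives to emit ``ghg`` kg CO2 eq.

    Reported rounded half-up to whole km by default; pass ``rounded=False``
    for the unrounded value (the function is then exactly linear in ghg).
    """
    if ghg < 0:
        raise ValidationError("ghg must be >= 0; pass the magnitude of a reduction")
    km = ghg / equiv.kg_co2e_per_mile * equiv.km_per_mile
    return round_half_up(km, 0) if rounded else km
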