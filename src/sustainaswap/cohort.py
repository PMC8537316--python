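"""Cohort-level modelling: apply a swap to individual intakes and score NRVs.

An :class:`IntakeRecord` holds one person's FFQ-derived daily nutrient
intake plus how many serves of the reference food they eat per week. A
weekly swap changes daily intake by one seventh of the per-serve nutrient
delta. Two application modes are supported:

``per_individual``
    only people satisfying an eligibility rule (by default, at least one
    reference-food serve per week) receive the shift — the realistic
    model, under which the population mean moves by
    eligible_fraction x delta/7;

``uniform``
    every record is shifted, so summary statistics translate rigidly:
    the mean, median and every quantile move by exactly delta/7 while the
    SD and IQR width are untouched. This mode reproduces published
    before/after summary tables that were produced by shifting summary
    statistics directly.

Compliance with a Nutrient Reference Value (NRV) is intake >= threshold;
an Adequate Intake (AI) is scored the same way as an Estimated Average
Requirement (EAR).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from ._rounding import round_half_up
from .errors import ConfigurationError, SchemaError, ValidationError
from .foods import NutrientVector
from .footprint import Frequency
from .swap import SwapResult

__all__ = [
    "NRVKind",
    "NRVEntry",
    "IntakeRecord",
    "ShiftMode",
    "COHORT_COLUMNS",
    "default_eligibility",
    "apply_swap_to_cohort",
    "nrv_compliance",
    "summarize_cohort",
    "load_cohort",
    "write_cohort",
    "load_nrv_table",
    "bundled_nrvs",
]


class NRVKind(str, Enum):
    EAR = "EAR"  # estimated average requirement
    AI = "AI"    # adequate intake


@dataclass(frozen=True)
class NRVEntry:
    """One nutrient's reference threshold, in that nutrient's daily units."""

    nutrient: str
    threshold: float
    kind: NRVKind = NRVKind.EAR

    def __post_init__(self) -> None:
        if self.nutrient not in NutrientVector.field_names():
            raise ValidationError(f"unknown nutrient {self.nutrient!r}")
        if self.threshold <= 0:
            raise ValidationError(f"NRV threshold must be > 0 for {self.nutrient}")
        object.__setattr__(self, "kind", NRVKind(self.kind))


@dataclass(frozen=True)
class IntakeRecord:
    """One person's daily nutrient intake and weekly reference-food serves."""

    person_id: str
    daily_intake: NutrientVector
    reference_serves_per_week: float = 0.0

    def __post_init__(self) -> None:
        self.daily_intake.validate_nonnegative(context=str(self.person_id))
        if self.reference_serves_per_week < 0:
            raise ValidationError(
                f"negative serves/week for {self.person_id}"
            )


class ShiftMode(str, Enum):
    PER_INDIVIDUAL = "per_individual"
    UNIFORM = "uniform"


def default_eligibility(record: IntakeRecord) -> bool:
    """Eligible to receive the swap: consumes the reference food weekly (>= 1)."""
    return record.reference_serves_per_week >= 1


def apply_swap_to_cohort(
    cohort: Sequence[IntakeRecord],
    result: SwapResult,
    eligibility: Callable[[IntakeRecord], bool] = default_eligibility,
    mode: ShiftMode | str = ShiftMode.PER_INDIVIDUAL,
) -> list[IntakeRecord]:
    """Return a new cohort with the weekly swap applied to daily intakes.

    Intakes are clipped at zero: a swap cannot drive a daily intake
    negative (relevant only for extreme deltas on low consumers).
    """
    mode = ShiftMode(mode)
    if result.scenario.scaling.frequency is not Frequency.WEEKLY:
        raise ConfigurationError(
            "cohort modelling divides the per-serve delta by 7 and requires a "
            f"weekly swap; got frequency={result.scenario.scaling.frequency.value!r}"
        )
    daily_delta = result.nutrient_delta * (1.0 / 7.0)
    out = []
    for rec in cohort:
        if mode is ShiftMode.UNIFORM or eligibility(rec):
            shifted = rec.daily_intake + daily_delta
            clipped = NutrientVector(**{
                k: max(v, 0.0) for k, v in shifted.as_dict().items()
            })
            out.append(replace(rec, daily_intake=clipped))
        else:
            out.append(rec)
    return out


def nrv_compliance(
    cohort: Sequence[IntakeRecord], nrvs: Iterable[NRVEntry]
) -> dict[str, tuple[int, float]]:
    """Per nutrient: (count meeting the NRV, percentage of cohort, whole %)."""
    if not cohort:
        raise ValidationError("empty cohort")
    n = len(cohort)
    out = {}
    for nrv in nrvs:
        met = sum(
            1 for rec in cohort
            if getattr(rec.daily_intake, nrv.nutrient) >= nrv.threshold
        )
        out[nrv.nutrient] = (met, round_half_up(100.0 * met / n, 0))
    return out


def summarize_cohort(
    cohort: Sequence[IntakeRecord], nrvs: Sequence[NRVEntry]
) -> pd.DataFrame:
    """Summary table, one row per NRV nutrient.

    Columns: nrv_kind, nrv, mean, sd (n-1 denominator), median, q25, q75,
    met_n, met_pct. Quantiles use linear interpolation between order
    statistics. A single-record cohort reports sd 0 with a warning.
    """
    if not cohort:
        raise ValidationError("empty cohort")
    compliance = nrv_compliance(cohort, nrvs)
    rows = []
    for nrv in nrvs:
        x = np.array([getattr(r.daily_intake, nrv.nutrient) for r in cohort])
        if len(x) > 1:
            sd = float(np.std(x, ddof=1))
        else:
            warnings.warn("single-record cohort: SD reported as 0", stacklevel=2)
            sd = 0.0
        met_n, met_pct = compliance[nrv.nutrient]
        rows.append({
            "nutrient": nrv.nutrient,
            "nrv_kind": nrv.kind.value,
            "nrv": nrv.threshold,
            "mean": float(np.mean(x)),
            "sd": sd,
            "median": float(np.quantile(x, 0.5)),
            "q25": float(np.quantile(x, 0.25)),
            "q75": float(np.quantile(x, 0.75)),
            "met_n": met_n,
            "met_pct": met_pct,
        })
    return pd.DataFrame(rows)


#: Canonical cohort CSV header.
COHORT_COLUMNS: tuple[str, ...] = (
    "person_id", "protein_g", "fiber_g", "iron_mg", "zinc_mg", "calcium_mg",
    "folate_dfe_ug", "beef_serves_per_week",
)

_COL_TO_FIELD = {
    "protein_g": "protein",
    "fiber_g": "dietary_fiber",
    "iron_mg": "iron",
    "zinc_mg": "zinc",
    "calcium_mg": "calcium",
    "folate_dfe_ug": "folate_dfe",
}


def load_cohort(path: str | Path) -> list[IntakeRecord]:
    """Read a cohort CSV (see :data:`COHORT_COLUMNS`)."""
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return [
        IntakeRecord(
            person_id=str(r["person_id"]),
            daily_intake=NutrientVector(**{
                field: float(r[col]) for col, field in _COL_TO_FIELD.items()
            }),
            reference_serves_per_week=float(r["beef_serves_per_week"]),
        )
        for _, r in df.iterrows()
    ]


def write_cohort(cohort: Sequence[IntakeRecord], path: str | Path) -> None:
    """Write a cohort to CSV in the canonical layout (unrounded values)."""
    rows = []
    for rec in cohort:
        row = {"person_id": rec.person_id}
        for col, field in _COL_TO_FIELD.items():
            row[col] = getattr(rec.daily_intake, field)
        row["beef_serves_per_week"] = rec.reference_serves_per_week
        rows.append(row)
    pd.DataFrame(rows, columns=list(COHORT_COLUMNS)).to_csv(path, index=False)


def load_nrv_table(path: str | Path) -> list[NRVEntry]:
    """Read an NRV CSV with columns nutrient, kind, threshold."""
    df = pd.read_csv(path, comment="#")
    for col in ("nutrient", "kind", "threshold"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column(s) {col}")
    return [
        NRVEntry(nutrient=str(r["nutrient"]), threshold=float(r["threshold"]),
                 kind=NRVKind(str(r["kind"])))
        for _, r in df.iterrows()
    ]


def bundled_nrvs() -> list[NRVEntry]:
    """Pregnancy NRV thresholds bundled with the package."""
    from importlib import resources

    with resources.as_file(
        resources.files("sustainaswap.data").joinpath("nrv_pregnancy.csv")
    ) as p:
        return load_nrv_table(p)
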