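"""End-to-end pipeline: configuration, orchestration, report bundle.

A :class:`RunConfig` (built directly or loaded from YAML) names the food
table, the swap scenarios, the cohort source (a CSV or a synthetic-cohort
configuration), the NRV table and the model constants. Running it emits
four CSV reports into the output directory:

- ``matched_serves.csv``   nutrient comparison of reference vs alternatives
- ``footprints.csv``       per-serve and per-pregnancy footprints
- ``swap_deltas.csv``      signed nutrient/footprint deltas per scenario
- ``cohort_summary.csv``   cohort summary before/after the first scenario

Outputs are deterministic given the configuration and seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bioavailability import IronAbsorptionParams
from .cohort import (
    IntakeRecord,
    ShiftMode,
    bundled_nrvs,
    load_cohort,
    load_nrv_table,
    summarize_cohort,
)
from .errors import ConfigurationError
from .foods import FoodTable, bundled_food_table, load_food_table
from .footprint import PregnancyScaling, VehicleEquivalence
from .matching import MatchBasis
from .reports import footprint_table, matched_serve_table
from .swap import SwapScenario, evaluate_swap, swap_report
from .synthetic import SyntheticCohortConfig, generate_cohort
from .cohort import apply_swap_to_cohort, default_eligibility

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineStageError"]


class PipelineStageError(ConfigurationError):
    """A stage failed; carries the stage name and the underlying error."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[stage: {stage}] {err}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs."""

    scenarios: list[SwapScenario]
    food_table: str | None = None        # path; None -> bundled fixture
    cohort: str | None = None            # path; None -> synthetic cohort
    nrv_table: str | None = None         # path; None -> bundled thresholds
    outdir: str = "reports"
    iron_params: IronAbsorptionParams = field(default_factory=IronAbsorptionParams)
    vehicle: VehicleEquivalence = field(default_factory=VehicleEquivalence)
    shift_mode: ShiftMode = ShiftMode.PER_INDIVIDUAL
    synthetic: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ConfigurationError("at least one swap scenario required")
        object.__setattr__(self, "shift_mode", ShiftMode(self.shift_mode))

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        """Load a run configuration from a YAML file.

        Recognised keys: ``food_table``, ``cohort``, ``nrv_table``,
        ``outdir``, ``seed``, ``shift_mode``, ``scenarios`` (list of
        mappings with ``reference``, ``alternative`` and optional
        ``basis``/``frequency``/``duration_days``), ``iron_params``,
        ``vehicle`` and ``synthetic`` (field mappings for the respective
        dataclasses). A ``seed`` argument overrides the file.
        """
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scenarios = []
        for sc in raw.get("scenarios", []):
            scaling = PregnancyScaling(
                duration_days=float(sc.get("duration_days", 270)),
                frequency=sc.get("frequency", "weekly"),
            )
            scenarios.append(SwapScenario(
                reference=sc["reference"],
                alternative=sc["alternative"],
                basis=MatchBasis(sc.get("basis", "energy")),
                scaling=scaling,
            ))
        file_seed = int(raw.get("seed", 0))
        use_seed = file_seed if seed is None else seed
        synth_kwargs = dict(raw.get("synthetic", {}))
        synth_kwargs.setdefault("seed", use_seed)
        return cls(
            scenarios=scenarios,
            food_table=raw.get("food_table"),
            cohort=raw.get("cohort"),
            nrv_table=raw.get("nrv_table"),
            outdir=raw.get("outdir", "reports"),
            iron_params=IronAbsorptionParams(**raw.get("iron_params", {})),
            vehicle=VehicleEquivalence(**raw.get("vehicle", {})),
            shift_mode=ShiftMode(raw.get("shift_mode", "per_individual")),
            synthetic=SyntheticCohortConfig(**synth_kwargs),
            seed=use_seed,
        )


def _load_inputs(config: RunConfig) -> tuple[FoodTable, list[IntakeRecord], list]:
    table = (load_food_table(config.food_table) if config.food_table
             else bundled_food_table())
    if config.cohort:
        cohort = load_cohort(config.cohort)
    else:
        synth = config.synthetic
        if synth.seed != config.seed:
            from dataclasses import replace
            synth = replace(synth, seed=config.seed)
        cohort = generate_cohort(synth)
    nrvs = load_nrv_table(config.nrv_table) if config.nrv_table else bundled_nrvs()
    return table, cohort, nrvs


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run all stages and write the four CSV reports to ``config.outdir``."""
    logger.info(
        "sustainaswap %s | seed=%d | iron=%s | vehicle=%s",
        __version__, config.seed, config.iron_params, config.vehicle,
    )
    stage = "inputs"
    try:
        table, cohort, nrvs = _load_inputs(config)
        primary = config.scenarios[0]

        stage = "matched_serves"
        serves_df = matched_serve_table(
            table, primary.reference, primary.basis, config.iron_params)

        stage = "footprints"
        fp_df = footprint_table(
            table, primary.reference, primary.basis, primary.scaling, config.vehicle)

        stage = "swap_deltas"
        deltas_df = swap_report(table, config.scenarios,
                                config.iron_params, config.vehicle)

        stage = "cohort_model"
        result = evaluate_swap(table, primary, config.iron_params, config.vehicle)
        before = summarize_cohort(cohort, nrvs)
        after_cohort = apply_swap_to_cohort(
            cohort, result, default_eligibility, config.shift_mode)
        after = summarize_cohort(after_cohort, nrvs)
        before.insert(0, "stage", "original")
        after.insert(0, "stage", "modeled")
        cohort_df = pd.concat([before, after], ignore_index=True)
    except Exception as err:
        raise PipelineStageError(stage, err) from err

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = {
        "matched_serves": serves_df,
        "footprints": fp_df,
        "swap_deltas": deltas_df,
        "cohort_summary": cohort_df,
    }
    for name, df in bundle.items():
        df.to_csv(outdir / f"{name}.csv", index=False, float_format="%.6g")
    logger.info("wrote %d reports to %s", len(bundle), outdir)
    return bundle
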