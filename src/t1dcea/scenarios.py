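"""Declarative scenario runner: base case, indirect-cost secondary case,
one-way sensitivity analyses and subgroup analyses.

Subgroup scenarios recompute the intervention effects from the *subgroup's
own* mean baseline HbA1c / age / severe-hypo rate via the effect regressions,
so a poorly-controlled (HbA1c > 9%) subgroup receives a larger HbA1c benefit
— the mechanism behind the subgroup divergence of the ICER.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import pandas as pd

from .cohort import PatientProfile
from .costing import CostTable, DisabilityDurations, SalaryTable
from .disease import DiseaseParams
from .economics import DiscountSpec
from .effects import EffectCoefficients
from .model import CEAModel, CEAResults
from .utility import UtilityTable

__all__ = [
    "SUBGROUPS",
    "ScenarioSpec",
    "RunSettings",
    "EmptySubgroupError",
    "run_scenario",
    "run_suite",
    "default_suite",
    "suite_report",
]

SUBGROUPS: Dict[str, Callable[[PatientProfile], bool]] = {
    "hba1c_le_9": lambda p: p.hba1c <= 9.0,
    "hba1c_gt_9": lambda p: p.hba1c > 9.0,
    "duration_le_10": lambda p: p.diabetes_duration <= 10.0,
    "duration_gt_10": lambda p: p.diabetes_duration > 10.0,
}


class EmptySubgroupError(ValueError):
    """The subgroup filter removed every patient."""


@dataclass(frozen=True)
class ScenarioSpec:
    """One scenario: optional overrides on top of the base-case pipeline."""

    name: str
    include_indirect_costs: bool = False
    hba1c_effect_override: Optional[float] = None  # percentage points (e.g. -0.6)
    discount_override: Optional[DiscountSpec] = None
    subgroup: Optional[str] = None  # key into SUBGROUPS
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.subgroup is not None and self.subgroup not in SUBGROUPS:
            raise ValueError(
                f"unknown subgroup {self.subgroup!r}; choose from {sorted(SUBGROUPS)}"
            )
        if self.hba1c_effect_override is not None and not (
            -10.0 <= self.hba1c_effect_override <= 10.0
        ):
            raise ValueError("hba1c_effect_override outside plausible range")


@dataclass
class RunSettings:
    """Shared (non-scenario) configuration for a suite run."""

    cost_table: Optional[CostTable] = None
    utility_table: Optional[UtilityTable] = None
    effect_coefs: Optional[EffectCoefficients] = None
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    horizon: int = 70
    sim_seed: int = 0
    disability: Optional[DisabilityDurations] = None
    salary: Optional[SalaryTable] = None


def run_scenario(
    spec: ScenarioSpec,
    cohort: Sequence[PatientProfile],
    params: Optional[DiseaseParams] = None,
    settings: Optional[RunSettings] = None,
) -> CEAResults:
    """Apply the scenario's overrides/filters and fit both arms (paired)."""
    settings = settings or RunSettings()
    sub = list(cohort)
    if spec.subgroup is not None:
        pred = SUBGROUPS[spec.subgroup]
        sub = [p for p in sub if pred(p)]
        if not sub:
            raise EmptySubgroupError(
                f"scenario {spec.name!r}: subgroup {spec.subgroup!r} is empty"
            )
    model = CEAModel(
        sub,
        disease_params=params,
        cost_table=settings.cost_table,
        utility_table=settings.utility_table,
        effect_coefs=settings.effect_coefs,
        delta_hba1c_override=spec.hba1c_effect_override,
        discount=spec.discount_override or settings.discount,
        horizon=settings.horizon,
        include_indirect=spec.include_indirect_costs,
        disability=settings.disability,
        salary=settings.salary,
    )
    seed = spec.seed if spec.seed is not None else settings.sim_seed
    return model.fit(seed=seed, name=spec.name)


def default_suite() -> List[ScenarioSpec]:
    """The nine standard rows: base case, indirect-cost secondary case,
    halved HbA1c benefit, two discount-rate combinations, four subgroups."""
    return [
        ScenarioSpec("base_case"),
        ScenarioSpec("secondary_direct_and_indirect", include_indirect_costs=True),
        ScenarioSpec("hba1c_benefit_halved_minus_0_6", hba1c_effect_override=-0.6),
        ScenarioSpec(
            "discount_3pct_costs_0pct_benefits",
            discount_override=DiscountSpec(rate_costs=0.03, rate_effects=0.0),
        ),
        ScenarioSpec(
            "discount_7pct_costs_7pct_benefits",
            discount_override=DiscountSpec(rate_costs=0.07, rate_effects=0.07),
        ),
        ScenarioSpec("subgroup_hba1c_le_9", subgroup="hba1c_le_9"),
        ScenarioSpec("subgroup_hba1c_gt_9", subgroup="hba1c_gt_9"),
        ScenarioSpec("subgroup_duration_le_10", subgroup="duration_le_10"),
        ScenarioSpec("subgroup_duration_gt_10", subgroup="duration_gt_10"),
    ]


def _dedupe(names: List[str]) -> List[str]:
    seen: Dict[str, int] = {}
    out = []
    for n in names:
        if n in seen:
            seen[n] += 1
            out.append(f"{n}_{seen[n]}")
        else:
            seen[n] = 1
            out.append(n)
    return out


def run_suite(
    specs: Sequence[ScenarioSpec],
    cohort: Sequence[PatientProfile],
    params: Optional[DiseaseParams] = None,
    settings: Optional[RunSettings] = None,
) -> List[CEAResults]:
    """Run every scenario; duplicate names are suffixed uniquely."""
    if len(specs) == 0:
        raise ValueError("need at least one scenario")
    names = _dedupe([s.name for s in specs])
    results = []
    for spec, name in zip(specs, names):
        res = run_scenario(spec, cohort, params, settings)
        res.name = name
        results.append(res)
    return results


def suite_report(results: Sequence[CEAResults]) -> pd.DataFrame:
    """One row per scenario, shaped like a sensitivity-analysis table."""
    rows = []
    for r in results:
        rate = r.model.cost_table.exchange_rate_mxn_per_usd
        iq = r.icer_per_qaly
        rows.append(
            {
                "scenario": r.name,
                "n": r.csii.n,
                "icer_mxn_per_qaly": iq.value,
                "icer_usd_per_qaly": iq.value / rate if iq.value is not None else None,
                "icer_flag": iq.flag,
                "csii_total_cost_mxn": r.csii.cost_total,
                "csii_total_cost_usd": r.csii.cost_total / rate,
                "csii_qalys": r.csii.qalys,
                "mdi_total_cost_mxn": r.mdi.cost_total,
                "mdi_total_cost_usd": r.mdi.cost_total / rate,
                "mdi_qalys": r.mdi.qalys,
                "delta_cost_mxn": r.delta_cost,
                "delta_qalys": r.delta_qalys,
            }
        )
    return pd.DataFrame(rows).set_index("scenario")
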