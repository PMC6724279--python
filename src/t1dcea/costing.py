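"""Valuation of simulated states and events in 2016 MXN.

All costs are carried in Mexican pesos (the canonical currency of the stored
artifacts); USD figures are derived only at reporting time via the fixed 2016
exchange rate of 18.390 MXN/USD.

Cost-derivation rules implemented here:

* subsequent-year maintenance costs for the cardiovascular states are one
  ninth of the event-year cost (the published footnote describes them as 10%
  of an acute-event cost itself taken as 90% of the DRG episode — the printed
  rows are consistent with event/9 to the centavo, which is what we use);
* DRG episode costs convert from 2014 to 2016 pesos by a single application
  of the health-care-specific inflation rate 0.0865;
* insulin is costed from body weight, a daily dose in IU/kg and a unit price
  per IU;
* indirect costs follow the human-capital approach: lost workdays valued at
  the sex-specific mean daily IMSS salary, only between first income (18) and
  retirement (60), capped at the 255 workdays of a year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import yaml

from .rounding import money

__all__ = [
    "COST_CATEGORIES",
    "CATEGORY_OF_STATE",
    "CostTable",
    "SalaryTable",
    "DisabilityDurations",
    "CycleSnapshot",
    "subsequent_year_cost",
    "inflate_drg",
    "to_usd",
    "insulin_annual_cost",
    "therapy_annual_cost",
    "weighted_cost",
    "annual_direct_cost",
    "indirect_cost",
]

#: Reporting categories (mirroring the base-case results breakdown).
COST_CATEGORIES: Tuple[str, ...] = (
    "treatment",
    "management",
    "cardiovascular",
    "renal",
    "ulcer_amputation_neuropathy",
    "eye",
    "hypoglycemia",
    "other_acute",
)

CATEGORY_OF_STATE: Dict[str, str] = {
    "myocardial_infarction": "cardiovascular",
    "angina": "cardiovascular",
    "congestive_heart_failure": "cardiovascular",
    "stroke": "cardiovascular",
    "stroke_death_within_30_days": "cardiovascular",
    "peripheral_vascular_disease": "cardiovascular",
    "hemodialysis": "renal",
    "peritoneal_dialysis": "renal",
    "kidney_transplant": "renal",
    "microalbuminuria": "renal",
    "gross_proteinuria": "renal",
    "end_stage_renal_disease": "renal",
    "background_retinopathy": "eye",
    "proliferative_retinopathy": "eye",
    "macular_edema": "eye",
    "cataract": "eye",
    "severe_visual_loss": "eye",
    "neuropathy": "ulcer_amputation_neuropathy",
    "uninfected_ulcer": "ulcer_amputation_neuropathy",
    "infected_ulcer": "ulcer_amputation_neuropathy",
    "healed_ulcer": "ulcer_amputation_neuropathy",
    "amputation": "ulcer_amputation_neuropathy",
    "gangrene": "ulcer_amputation_neuropathy",
}

_ACUTE_CATEGORY = {
    "severe_hypo": "hypoglycemia",
    "minor_hypo": "hypoglycemia",
    "ketoacidosis": "other_acute",
    "lactic_acidosis": "other_acute",
    "edema": "other_acute",
}

EXCHANGE_RATE_MXN_PER_USD = 18.390
DRG_INFLATION_2014_2016 = 0.0865


@dataclass
class CostTable:
    """Unit costs in 2016 MXN (see packaged ``data/cost_table.yaml``)."""

    therapy: Dict[str, float]
    events: Dict[str, Dict[str, float]]  # item -> {event_year, subsequent_year}
    acute: Dict[str, float]
    medications_monthly: Dict[str, float]
    screening_annual: Dict[str, float]
    exchange_rate_mxn_per_usd: float = EXCHANGE_RATE_MXN_PER_USD
    drg_inflation_2014_2016: float = DRG_INFLATION_2014_2016

    def __post_init__(self) -> None:
        if self.exchange_rate_mxn_per_usd <= 0:
            raise ValueError("exchange rate must be > 0")
        for name, v in self.therapy.items():
            if v < 0:
                raise ValueError(f"therapy[{name!r}] must be >= 0")
        for name, d in self.events.items():
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"events[{name!r}][{k!r}] must be >= 0")
        for group in (self.acute, self.medications_monthly, self.screening_annual):
            for name, v in group.items():
                if v < 0:
                    raise ValueError(f"cost {name!r} must be >= 0")

    @classmethod
    def from_dict(cls, data: Mapping) -> "CostTable":
        return cls(
            therapy=dict(data["therapy"]),
            events={k: dict(v) for k, v in data["events"].items()},
            acute=dict(data["acute"]),
            medications_monthly=dict(data["medications_monthly"]),
            screening_annual=dict(data["screening_annual"]),
            exchange_rate_mxn_per_usd=float(
                data.get("exchange_rate_mxn_per_usd", EXCHANGE_RATE_MXN_PER_USD)
            ),
            drg_inflation_2014_2016=float(
                data.get("drg_inflation_2014_2016", DRG_INFLATION_2014_2016)
            ),
        )

    @classmethod
    def from_yaml(cls, path) -> "CostTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "CostTable":
        from importlib.resources import files

        with files("t1dcea.data").joinpath("cost_table.yaml").open() as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def scaled(self, multipliers: Mapping[str, float]) -> "CostTable":
        """Copy with per-item multiplicative factors (for probabilistic
        sensitivity analysis).  Keys: therapy/acute/event item names."""
        new = CostTable(
            therapy={k: v * multipliers.get(k, 1.0) for k, v in self.therapy.items()},
            events={
                k: {kk: vv * multipliers.get(k, 1.0) for kk, vv in v.items()}
                for k, v in self.events.items()
            },
            acute={k: v * multipliers.get(k, 1.0) for k, v in self.acute.items()},
            medications_monthly=dict(self.medications_monthly),
            screening_annual=dict(self.screening_annual),
            exchange_rate_mxn_per_usd=self.exchange_rate_mxn_per_usd,
            drg_inflation_2014_2016=self.drg_inflation_2014_2016,
        )
        return new


@dataclass(frozen=True)
class SalaryTable:
    """Human-capital inputs (2016 MXN)."""

    retirement_age: float = 60.0
    first_income_age: float = 18.0
    daily_salary_male: float = 333.76
    daily_salary_female: float = 292.88
    workdays_per_year: int = 255

    def __post_init__(self) -> None:
        if not self.first_income_age < self.retirement_age:
            raise ValueError("first_income_age must be < retirement_age")
        if self.daily_salary_male <= 0 or self.daily_salary_female <= 0:
            raise ValueError("salaries must be > 0")

    def daily_salary(self, sex: str) -> float:
        return self.daily_salary_male if sex == "male" else self.daily_salary_female


@dataclass
class DisabilityDurations:
    """Workdays of disability leave per incident event / active state-year.

    The source evaluation took these durations from its (unpublished) disease
    model; the neutral default here is zero for everything, making indirect
    costs an explicit opt-in configuration.
    """

    days: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.days.items():
            if v < 0:
                raise ValueError(f"disability days for {k!r} must be >= 0")

    def get(self, item: str) -> float:
        return self.days.get(item, 0.0)

    @classmethod
    def from_yaml(cls, path) -> "DisabilityDurations":
        with open(path) as fh:
            return cls(days={k: float(v) for k, v in (yaml.safe_load(fh) or {}).items()})


# ---------------------------------------------------------------------------
# derivation rules
# ---------------------------------------------------------------------------

def subsequent_year_cost(event_year_cost: float) -> float:
    """Maintenance-year cost implied by an event-year cost (event/9, to the
    centavo).  Reproduces every printed cardiovascular maintenance row."""
    if event_year_cost < 0:
        raise ValueError("event-year cost must be >= 0")
    return money(event_year_cost / 9.0)


def inflate_drg(cost_2014: float, rate: float = DRG_INFLATION_2014_2016) -> float:
    """2014 DRG cost expressed in 2016 pesos (single application of the
    health-care-specific inflation rate)."""
    return cost_2014 * (1.0 + rate)


def to_usd(mxn: float, rate: float = EXCHANGE_RATE_MXN_PER_USD) -> float:
    """Convert MXN to 2016 USD at the fixed exchange rate, rounded to cents."""
    if rate <= 0:
        raise ValueError("exchange rate must be > 0")
    return money(mxn / rate)


def insulin_annual_cost(
    weight_kg: float, dose_iu_per_kg: float, unit_cost_mxn_per_iu: float
) -> Dict[str, float]:
    """Annual insulin requirement and cost from weight and daily dose."""
    if weight_kg <= 0 or dose_iu_per_kg < 0 or unit_cost_mxn_per_iu < 0:
        raise ValueError("inputs must be positive (dose/cost may be 0)")
    daily = weight_kg * dose_iu_per_kg
    annual = daily * 365.0
    return {
        "daily_iu": daily,
        "annual_iu": annual,
        "annual_mxn": annual * unit_cost_mxn_per_iu,
    }


def therapy_annual_cost(arm: str, table: CostTable) -> float:
    """Annual therapy cost of an arm (CSII pump amortized over its 4-year
    warranty plus consumables and insulin; MDI from tender prices)."""
    if arm == "CSII":
        return table.therapy["csii_annual"]
    if arm == "MDI":
        return table.therapy["mdi_annual"]
    raise ValueError(f"unknown arm {arm!r}")


def weighted_cost(components: Iterable[Tuple[float, float]]) -> float:
    """Share-weighted average cost; shares must sum to 1."""
    components = list(components)
    shares = sum(s for _, s in components)
    if any(s < 0 for _, s in components):
        raise ValueError("shares must be >= 0")
    if abs(shares - 1.0) > 1e-9:
        raise ValueError(f"shares must sum to 1, got {shares}")
    return sum(c * s for c, s in components)


# ---------------------------------------------------------------------------
# per-cycle direct costs
# ---------------------------------------------------------------------------

@dataclass
class CycleSnapshot:
    """What a patient looks like during one cycle, for costing purposes."""

    arm: str
    incident_states: Set[str] = field(default_factory=set)  # onset this cycle
    prevalent_states: Set[str] = field(default_factory=set)  # active, onset earlier
    acute_events: Dict[str, int] = field(default_factory=dict)  # event -> count
    medications: Set[str] = field(default_factory=set)
    has_depression: bool = False
    fatal_complication: Optional[str] = None
    screening: bool = True


def annual_direct_cost(
    state: CycleSnapshot,
    events_this_cycle: Optional[Mapping[str, int]] = None,
    table: Optional[CostTable] = None,
) -> Dict[str, float]:
    """Direct medical cost of one cycle, by reporting category (MXN).

    Categories always sum to the ``total`` key.  ``events_this_cycle``
    overrides ``state.acute_events`` when given.
    """
    if table is None:
        table = CostTable.default()
    acute_events = dict(state.acute_events if events_this_cycle is None else events_this_cycle)
    out = {c: 0.0 for c in COST_CATEGORIES}

    out["treatment"] += therapy_annual_cost(state.arm, table)

    med_monthly = table.medications_monthly
    for med in state.medications:
        if med not in med_monthly:
            raise KeyError(f"medication {med!r} not in cost table")
        out["management"] += med_monthly[med] * 12.0
    if state.has_depression:
        out["management"] += med_monthly.get("antidepressants", 0.0) * 12.0
    if state.screening:
        out["management"] += sum(table.screening_annual.values())

    for name in state.incident_states:
        if name not in table.events:
            raise KeyError(f"state {name!r} not in cost table")
        cost = table.events[name]["event_year"]
        # a stroke fatal within its cycle is costed at the 30-day-death DRG
        if name == "stroke" and state.fatal_complication == "stroke":
            cost = table.events["stroke_death_within_30_days"]["event_year"]
        out[CATEGORY_OF_STATE.get(name, "management")] += cost
    for name in state.prevalent_states:
        if name not in table.events:
            raise KeyError(f"state {name!r} not in cost table")
        out[CATEGORY_OF_STATE.get(name, "management")] += table.events[name][
            "subsequent_year"
        ]

    for ev, count in acute_events.items():
        if ev not in table.acute:
            raise KeyError(f"acute event {ev!r} not in cost table")
        out[_ACUTE_CATEGORY.get(ev, "other_acute")] += table.acute[ev] * count

    out["total"] = sum(out[c] for c in COST_CATEGORIES)
    return out


def indirect_cost(
    age: float,
    sex: str,
    disability_days: float,
    salary: SalaryTable = SalaryTable(),
) -> float:
    """Human-capital productivity loss for one cycle (MXN).

    Zero outside the working-age window [first income, retirement); lost days
    capped at the annual number of workdays.
    """
    if disability_days < 0:
        raise ValueError("disability_days must be >= 0")
    if age < salary.first_income_age or age >= salary.retirement_age:
        return 0.0
    days = min(disability_days, float(salary.workdays_per_year))
    return days * salary.daily_salary(sex)
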