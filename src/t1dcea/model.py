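"""Model/Results facade over the simulation pipeline.

:class:`CEAModel` bundles a cohort with disease parameters, cost and utility
tables and a discounting specification; :meth:`CEAModel.fit` runs both
treatment arms with common random numbers, values every trajectory and
returns a :class:`CEAResults` carrying per-arm totals, incremental outcomes,
ICERs and a ``summary()`` table.  Probabilistic sensitivity analysis
(:meth:`CEAModel.ceac`) and scenario analyses (:mod:`t1dcea.scenarios`) build
on the same objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from . import economics
from .cohort import CohortSpec, PatientProfile, default_imss_spec, generate_cohort
from .costing import CostTable, DisabilityDurations, SalaryTable
from .disease import ArmRun, DiseaseParams, default_disease_params, simulate_arm
from .economics import ArmTotals, DiscountSpec, ICER, aggregate, icer
from .effects import EffectCoefficients, TreatmentEffects, point_effects
from .utility import UtilityTable
from .valuation import value_run

__all__ = ["CEAModel", "CEAResults", "make_psa_runner"]


class CEAModel:
    """Two-arm (CSII vs MDI) cost-effectiveness microsimulation model.

    Parameters
    ----------
    cohort
        Baseline patients (see :mod:`t1dcea.cohort`).
    disease_params, cost_table, utility_table
        Config inputs; packaged defaults when omitted.
    effect_coefs
        Regression coefficients for the intervention effects; the effects are
        evaluated at the *cohort's own* mean HbA1c, mean age and severe-hypo
        rate (so subgroup models get subgroup-specific effects).
    delta_hba1c_override
        Replaces the regression-derived HbA1c change (sensitivity analyses).
    effects
        Fully-specified :class:`TreatmentEffects`, bypassing the regressions.
    discount, horizon, include_indirect, disability, salary
        Economics settings; base case is 5%/5% discounting over a 70-year
        horizon, direct costs only.
    """

    def __init__(
        self,
        cohort: Sequence[PatientProfile],
        disease_params: Optional[DiseaseParams] = None,
        cost_table: Optional[CostTable] = None,
        utility_table: Optional[UtilityTable] = None,
        effect_coefs: Optional[EffectCoefficients] = None,
        effects: Optional[TreatmentEffects] = None,
        delta_hba1c_override: Optional[float] = None,
        discount: Optional[DiscountSpec] = None,
        horizon: int = 70,
        include_indirect: bool = False,
        disability: Optional[DisabilityDurations] = None,
        salary: Optional[SalaryTable] = None,
    ):
        if len(cohort) == 0:
            raise ValueError("cohort is empty")
        if not 1 <= horizon <= 70:
            raise ValueError(f"horizon must be in [1, 70], got {horizon}")
        self.cohort = list(cohort)
        self.disease_params = disease_params or default_disease_params()
        self.cost_table = cost_table or CostTable.default()
        self.utility_table = utility_table or UtilityTable.default()
        self.effect_coefs = effect_coefs or EffectCoefficients()
        self.discount = discount or DiscountSpec()
        self.horizon = horizon
        self.include_indirect = include_indirect
        self.disability = disability
        self.salary = salary
        if effects is not None:
            self.effects = effects
        else:
            self.effects = point_effects(
                self.effect_coefs,
                baseline_hba1c=float(np.mean([p.hba1c for p in self.cohort])),
                mdi_rate=float(np.mean([p.severe_hypo_rate for p in self.cohort])),
                mean_age=float(np.mean([p.age for p in self.cohort])),
                delta_hba1c_override=delta_hba1c_override,
            )

    @classmethod
    def from_spec(
        cls,
        cohort_spec: Optional[CohortSpec] = None,
        n: Optional[int] = None,
        seed: int = 0,
        **kwargs,
    ) -> "CEAModel":
        """Build the model from a cohort spec (IMSS defaults when omitted)."""
        spec = cohort_spec or default_imss_spec()
        if n is not None:
            spec = spec.replace(n=n)
        return cls(generate_cohort(spec, seed=seed), **kwargs)

    # ------------------------------------------------------------------
    def run_arm(self, arm: str, seed: int = 0) -> ArmRun:
        """Simulate one arm (same seed on both arms pairs them)."""
        return simulate_arm(
            self.cohort, self.disease_params, self.effects, arm,
            horizon_years=self.horizon, seed=seed,
        )

    def _arm_totals(self, run: ArmRun) -> ArmTotals:
        costs, utils = value_run(
            run, self.cost_table, self.utility_table,
            include_indirect=self.include_indirect,
            disability=self.disability, salary=self.salary,
        )
        return aggregate(run, costs, utils, self.discount, arm=run.arm)

    def fit(self, seed: int = 0, name: str = "base_case") -> "CEAResults":
        """Run both arms with common random numbers and aggregate."""
        runs = {arm: self.run_arm(arm, seed=seed) for arm in ("CSII", "MDI")}
        totals = {arm: self._arm_totals(run) for arm, run in runs.items()}
        return CEAResults(
            name=name, model=self, seed=seed,
            csii=totals["CSII"], mdi=totals["MDI"], runs=runs,
        )

    # ------------------------------------------------------------------
    def ceac(
        self,
        n_outer: int = 1000,
        n_inner: int = 1000,
        cohort_spec: Optional[CohortSpec] = None,
        cost_cv: float = 0.2,
        wtp_grid=None,
        seed: int = 0,
    ) -> economics.CEACCurve:
        """Cost-effectiveness acceptability curve (1st + 2nd order MC)."""
        runner = make_psa_runner(
            self, n_inner=n_inner, cohort_spec=cohort_spec, cost_cv=cost_cv
        )
        return economics.ceac(
            runner, n_outer=n_outer, n_inner=n_inner,
            wtp_grid=wtp_grid, rng=np.random.default_rng(seed),
        )


@dataclass
class CEAResults:
    """Fitted two-arm results: totals, increments, ICERs, diagnostics."""

    name: str
    model: CEAModel
    seed: int
    csii: ArmTotals
    mdi: ArmTotals
    runs: Dict[str, ArmRun] = field(repr=False, default=None)

    # -- incremental outcomes (discounted) ------------------------------
    @property
    def delta_cost(self) -> float:
        return self.csii.cost_total - self.mdi.cost_total

    @property
    def delta_qalys(self) -> float:
        return self.csii.qalys - self.mdi.qalys

    @property
    def delta_life_years(self) -> float:
        return self.csii.life_years - self.mdi.life_years

    @property
    def icer_per_qaly(self) -> ICER:
        return icer(self.delta_cost, self.delta_qalys)

    @property
    def icer_per_lyg(self) -> ICER:
        return icer(self.delta_cost, self.delta_life_years)

    @property
    def dominance(self) -> str:
        return self.icer_per_qaly.flag

    def nmb(self, wtp: float) -> float:
        return economics.nmb(self.delta_cost, self.delta_qalys, wtp)

    # -- per-patient paired contrasts -----------------------------------
    @property
    def per_patient_delta_qalys(self) -> np.ndarray:
        return self.csii.per_patient_qalys - self.mdi.per_patient_qalys

    @property
    def per_patient_delta_cost(self) -> np.ndarray:
        return self.csii.per_patient_cost - self.mdi.per_patient_cost

    # -- reporting -------------------------------------------------------
    def summary(self) -> pd.DataFrame:
        """Base-case-style table: per-arm totals and the difference, with
        USD columns derived at the fixed exchange rate."""
        rate = self.model.cost_table.exchange_rate_mxn_per_usd
        rows = []

        def add(label, c, m, money=False):
            d = c - m
            row = {"outcome": label, "CSII": c, "MDI": m, "difference": d}
            if money:
                row.update(
                    {"CSII_usd": c / rate, "MDI_usd": m / rate, "difference_usd": d / rate}
                )
            rows.append(row)

        add("life_expectancy_discounted_years", self.csii.life_years, self.mdi.life_years)
        add(
            "life_expectancy_undiscounted_years",
            self.csii.life_years_undiscounted, self.mdi.life_years_undiscounted,
        )
        add("qalys", self.csii.qalys, self.mdi.qalys)
        add("total_cost_mxn", self.csii.cost_total, self.mdi.cost_total, money=True)
        cats = sorted(set(self.csii.cost_by_category) | set(self.mdi.cost_by_category))
        for c in cats:
            add(
                f"cost_{c}_mxn",
                self.csii.cost_by_category.get(c, 0.0),
                self.mdi.cost_by_category.get(c, 0.0),
                money=True,
            )
        df = pd.DataFrame(rows).set_index("outcome")
        for label, ic in (
            ("icer_per_qaly_mxn", self.icer_per_qaly),
            ("icer_per_lyg_mxn", self.icer_per_lyg),
        ):
            df.loc[label, "difference"] = ic.value if ic.value is not None else np.nan
            if ic.value is not None:
                df.loc[label, "difference_usd"] = ic.value / rate
        return df

    def to_dict(self) -> dict:
        iq, il = self.icer_per_qaly, self.icer_per_lyg
        return {
            "name": self.name,
            "n": self.csii.n,
            "seed": self.seed,
            "horizon": self.model.horizon,
            "discount": {
                "costs": self.model.discount.rate_costs,
                "effects": self.model.discount.rate_effects,
            },
            "effects": {
                "delta_hba1c": self.model.effects.delta_hba1c,
                "hypo_rate_ratio": self.model.effects.hypo_rate_ratio,
                "csii_hypo_rate": self.model.effects.csii_hypo_rate,
            },
            "csii": _totals_dict(self.csii),
            "mdi": _totals_dict(self.mdi),
            "delta_cost_mxn": self.delta_cost,
            "delta_qalys": self.delta_qalys,
            "delta_life_years": self.delta_life_years,
            "icer_per_qaly_mxn": iq.value,
            "icer_per_qaly_flag": iq.flag,
            "icer_per_lyg_mxn": il.value,
            "icer_per_lyg_flag": il.flag,
        }

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        iq = self.icer_per_qaly
        icer_s = f"{iq.value:,.0f} MXN/QALY" if iq.value is not None else iq.flag
        return (
            f"<CEAResults {self.name!r}: n={self.csii.n}, "
            f"dC={self.delta_cost:,.0f} MXN, dQALY={self.delta_qalys:.3f}, "
            f"ICER={icer_s}>"
        )


def _totals_dict(t: ArmTotals) -> dict:
    return {
        "cost_total_mxn": t.cost_total,
        "cost_total_undiscounted_mxn": t.cost_total_undiscounted,
        "cost_by_category_mxn": dict(t.cost_by_category),
        "life_years": t.life_years,
        "life_years_undiscounted": t.life_years_undiscounted,
        "qalys": t.qalys,
        "qalys_undiscounted": t.qalys_undiscounted,
    }


def make_psa_runner(
    base: CEAModel,
    n_inner: int = 1000,
    cohort_spec: Optional[CohortSpec] = None,
    cost_cv: float = 0.2,
):
    """One-outer-draw runner for :func:`t1dcea.economics.ceac`.

    Each call samples second-order parameters — the two HbA1c regression
    coefficients from normals at their published SEs, and gamma multipliers
    (mean 1, coefficient of variation ``cost_cv``) on the therapy, event and
    acute unit costs — generates a fresh ``n_inner``-patient cohort
    (first-order variability), simulates both arms with common random
    numbers, and returns ``(delta_cost, delta_qalys)``.
    """
    spec = cohort_spec or default_imss_spec()
    spec = spec.replace(n=n_inner)
    coefs = base.effect_coefs
    items = (
        list(base.cost_table.therapy)
        + list(base.cost_table.events)
        + list(base.cost_table.acute)
    )

    def runner(rng: np.random.Generator):
        cohort = generate_cohort(spec, seed=int(rng.integers(2**31)))
        if cost_cv > 0:
            shape = 1.0 / cost_cv**2
            mult = {
                it: rng.gamma(shape, 1.0 / shape) for it in items
            }
            table = base.cost_table.scaled(mult)
        else:
            table = base.cost_table
        model = CEAModel(
            cohort,
            disease_params=base.disease_params,
            cost_table=table,
            utility_table=base.utility_table,
            effect_coefs=coefs,
            discount=base.discount,
            horizon=base.horizon,
            include_indirect=base.include_indirect,
            disability=base.disability,
            salary=base.salary,
        )
        # second-order draw of the effect coefficients at the cohort means
        from .effects import sample_effects

        model.effects = sample_effects(
            coefs, rng,
            baseline_hba1c=float(np.mean([p.hba1c for p in cohort])),
            mdi_rate=float(np.mean([p.severe_hypo_rate for p in cohort])),
            mean_age=float(np.mean([p.age for p in cohort])),
        )
        res = model.fit(seed=int(rng.integers(2**31)))
        return res.delta_cost, res.delta_qalys

    return runner
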