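"""Discounting, aggregation, ICERs and the acceptability curve.

Conventions: annual cycles indexed from 0; cycle-end discounting with cycle 0
undiscounted, i.e. a quantity accrued in cycle ``t`` is weighted by
``(1 + r) ** -t``.  Costs and health effects may carry different rates
(base case: 5% for both).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "DiscountSpec",
    "ArmTotals",
    "ICER",
    "CEACCurve",
    "discount_factor",
    "aggregate",
    "icer",
    "nmb",
    "ceac",
    "default_wtp_grid",
    "WTP_1_GDP_MXN",
    "WTP_3_GDP_MXN",
]

#: 2016 Mexican willingness-to-pay anchors: one and three GDP per capita.
WTP_1_GDP_MXN = 153_000.0
WTP_3_GDP_MXN = 459_000.0


@dataclass(frozen=True)
class DiscountSpec:
    rate_costs: float = 0.05
    rate_effects: float = 0.05

    def __post_init__(self) -> None:
        if self.rate_costs < 0 or self.rate_effects < 0:
            raise ValueError("discount rates must be >= 0")


def discount_factor(t_years: int, rate: float) -> float:
    """``(1 + rate) ** -t`` (cycle 0 undiscounted)."""
    if t_years < 0:
        raise ValueError("t must be >= 0")
    return (1.0 + rate) ** (-t_years)


@dataclass
class ArmTotals:
    """Mean per-patient outcomes of one arm (costs in MXN)."""

    arm: str
    n: int
    cost_total: float  # discounted
    cost_total_undiscounted: float
    cost_by_category: Dict[str, float]  # discounted means
    life_years: float  # discounted
    life_years_undiscounted: float
    qalys: float  # discounted
    qalys_undiscounted: float
    # per-patient discounted values, kept for paired contrasts
    per_patient_cost: np.ndarray = field(repr=False, default=None)
    per_patient_qalys: np.ndarray = field(repr=False, default=None)
    per_patient_life_years: np.ndarray = field(repr=False, default=None)


def aggregate(
    trajectories: Sequence,
    costs_per_cycle: Sequence[Sequence[Mapping[str, float]]],
    utilities_per_cycle: Sequence[Sequence[float]],
    disc: DiscountSpec = DiscountSpec(),
    arm: str = "",
) -> ArmTotals:
    """Discounted per-patient sums averaged over the cohort.

    ``costs_per_cycle[i][t]`` is a category -> MXN mapping (the ``total`` key,
    if present, is ignored and recomputed); ``utilities_per_cycle[i][t]`` the
    cycle's utility weight.  Stream lengths must agree with each patient's
    lived cycles.
    """
    n = len(utilities_per_cycle)
    if len(costs_per_cycle) != n or (trajectories is not None and len(trajectories) != n):
        raise ValueError("misaligned inputs: cohort sizes differ")
    categories: List[str] = []
    for stream in costs_per_cycle:
        for cyc in stream:
            for k in cyc:
                if k != "total" and k not in categories:
                    categories.append(k)
        break  # category set taken from the first patient's stream
    # make sure later patients cannot introduce silently-dropped categories
    cat_set = set(categories)
    pp_cost = np.zeros(n)
    pp_cost_u = np.zeros(n)
    pp_ly = np.zeros(n)
    pp_ly_u = np.zeros(n)
    pp_q = np.zeros(n)
    pp_q_u = np.zeros(n)
    cat_sums = {c: 0.0 for c in categories}
    for i in range(n):
        costs = costs_per_cycle[i]
        utils = utilities_per_cycle[i]
        if len(costs) != len(utils):
            raise ValueError(f"patient {i}: cost and utility streams differ in length")
        if trajectories is not None and len(utils) != trajectories[i].n_cycles:
            raise ValueError(f"patient {i}: stream length != lived cycles")
        for t, (cyc, u) in enumerate(zip(costs, utils)):
            vc = (1.0 + disc.rate_costs) ** (-t)
            ve = (1.0 + disc.rate_effects) ** (-t)
            ctot = 0.0
            for k, v in cyc.items():
                if k == "total":
                    continue
                if k not in cat_set:
                    cat_set.add(k)
                    categories.append(k)
                    cat_sums[k] = 0.0
                cat_sums[k] += v * vc
                ctot += v
            pp_cost[i] += ctot * vc
            pp_cost_u[i] += ctot
            pp_ly[i] += ve
            pp_ly_u[i] += 1.0
            pp_q[i] += u * ve
            pp_q_u[i] += u
    return ArmTotals(
        arm=arm,
        n=n,
        cost_total=float(pp_cost.mean()),
        cost_total_undiscounted=float(pp_cost_u.mean()),
        cost_by_category={c: s / n for c, s in cat_sums.items()},
        life_years=float(pp_ly.mean()),
        life_years_undiscounted=float(pp_ly_u.mean()),
        qalys=float(pp_q.mean()),
        qalys_undiscounted=float(pp_q_u.mean()),
        per_patient_cost=pp_cost,
        per_patient_qalys=pp_q,
        per_patient_life_years=pp_ly,
    )


@dataclass(frozen=True)
class ICER:
    """An incremental cost-effectiveness ratio with dominance semantics.

    ``flag`` is ``"ok"`` (value defined), ``"dominant"`` (cheaper and more
    effective), ``"dominated"`` (costlier, not more effective) or
    ``"undefined"`` (cheaper, not more effective: no meaningful ratio).
    """

    value: Optional[float]
    flag: str
    delta_cost: float
    delta_effect: float

    def __float__(self) -> float:
        if self.value is None:
            raise ValueError(f"ICER is {self.flag}, not a number")
        return self.value


def icer(delta_cost: float, delta_effect: float) -> ICER:
    """Incremental cost-effectiveness ratio, flagging dominance instead of
    dividing by a non-positive effect."""
    if delta_effect > 0:
        if delta_cost < 0:
            return ICER(None, "dominant", delta_cost, delta_effect)
        return ICER(delta_cost / delta_effect, "ok", delta_cost, delta_effect)
    if delta_cost > 0:
        return ICER(None, "dominated", delta_cost, delta_effect)
    return ICER(None, "undefined", delta_cost, delta_effect)


def nmb(delta_cost: float, delta_effect: float, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return wtp * delta_effect - delta_cost


@dataclass
class CEACCurve:
    """Probability the intervention is cost-effective across WTP thresholds."""

    wtp: np.ndarray  # MXN per QALY
    probability: np.ndarray
    n_outer: int
    n_inner: int
    delta_costs: np.ndarray = field(repr=False, default=None)
    delta_effects: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if np.any((self.probability < 0) | (self.probability > 1)):
            raise ValueError("probabilities must be in [0, 1]")

    def probability_at(self, wtp: float) -> float:
        i = int(np.argmin(np.abs(self.wtp - wtp)))
        return float(self.probability[i])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"wtp_mxn_per_qaly": self.wtp, "probability": self.probability})

    def plot(self, ax=None, path=None):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        ax.plot(self.wtp, self.probability)
        for x, label in ((WTP_1_GDP_MXN, "1 GDP/capita"), (WTP_3_GDP_MXN, "3 GDP/capita")):
            ax.axvline(x, color="grey", linestyle="--", linewidth=0.8)
            ax.text(x, 1.02, label, ha="center", fontsize=8)
        ax.set_xlabel("Willingness to pay (MXN per QALY)")
        ax.set_ylabel("Probability cost-effective")
        ax.set_ylim(-0.02, 1.1)
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


def default_wtp_grid(step: float = 10_000.0, top: float = 600_000.0) -> np.ndarray:
    """0 to 600k MXN/QALY in 10k steps, spanning the 1- and 3-GDP anchors."""
    return np.arange(0.0, top + step / 2, step)


def ceac(
    model_runner: Callable[[np.random.Generator], Tuple[float, float]],
    n_outer: int = 1000,
    n_inner: int = 1000,
    wtp_grid: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> CEACCurve:
    """Cost-effectiveness acceptability curve from repeated model draws.

    ``model_runner(rng)`` performs one outer (second-order) draw — sampling
    parameters, simulating ``n_inner`` patients per arm with common random
    numbers — and returns ``(delta_cost, delta_qalys)``.  The probability at
    each threshold is the fraction of draws with positive net monetary
    benefit.  ``n_inner`` is informational here; the runner owns it.
    """
    if n_outer < 1 or n_inner < 1:
        raise ValueError("n_outer and n_inner must be >= 1")
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    if rng is None:
        rng = np.random.default_rng(seed)
    dc = np.empty(n_outer)
    de = np.empty(n_outer)
    for j in range(n_outer):
        dc[j], de[j] = model_runner(rng)
    prob = np.array([np.mean(w * de - dc > 0) for w in wtp_grid])
    return CEACCurve(
        wtp=np.asarray(wtp_grid, dtype=float),
        probability=prob,
        n_outer=n_outer,
        n_inner=n_inner,
        delta_costs=dc,
        delta_effects=de,
    )
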