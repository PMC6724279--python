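"""Turn simulated trajectories into per-cycle cost and utility streams.

This is the glue between the disease engine's state names and the cost /
utility vocabularies:

* myocardial infarction, stroke and amputation are *events with lasting
  impact*: their one-off disutility applies in the event cycle and the
  post-event health state (post-MI 0.73, post-stroke 0.621, post-amputation
  0.505) enters the minimum rule from the following cycle; their maintenance
  cost applies every later year.
* end-stage renal disease is valued through its treatment modality
  (hemodialysis / peritoneal dialysis / kidney transplant), assigned at onset.
* a healed ulcer ends the active-ulcer states (costing and disutility switch
  to the healed-ulcer follow-up).
* severe/minor hypoglycaemia events map to the major/minor hypoglycaemia
  one-off disutilities and per-event costs.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Set, Tuple

from .costing import CostTable, CycleSnapshot, DisabilityDurations, SalaryTable, annual_direct_cost, indirect_cost
from .disease import ACUTE_EVENTS, ArmRun, Trajectory
from .utility import UtilityTable, annual_utility

__all__ = ["value_trajectory", "value_run"]

#: events whose lasting impact is a new health-state baseline
_POST_STATE = {
    "myocardial_infarction": "post_myocardial_infarction",
    "stroke": "post_stroke",
    "amputation": "post_amputation",
}

#: healed ulcer ends the active ulcer states
_CLEARS = {"healed_ulcer": ("uninfected_ulcer", "infected_ulcer")}

#: acute event -> one-off disutility vocabulary
_ACUTE_UTILITY = {"severe_hypo": "major_hypo", "minor_hypo": "minor_hypo"}

#: baseline-profile flags with no dynamics/costs of their own
_NO_VALUATION = {"atrial_fibrillation", "left_ventricular_hypertrophy"}


def _baseline_sets(traj: Trajectory, util_vocab: Set[str]):
    """Initial (cycle-0 prevalent) cost and utility state sets.

    Built from the patient profile (not only the engine-tracked states), so
    baseline morbidity is valued even under reduced complication configs.
    """
    cost_active: Set[str] = set()
    util_active: Set[str] = set()
    has_depression = False
    modality = traj.esrd_modality
    baseline = set(traj.patient.complications)
    for s in baseline:
        if s in _NO_VALUATION:
            continue
        if s == "depression":
            has_depression = True
        elif s in ("end_stage_renal_disease", "kidney_transplant"):
            continue  # handled once via the modality below
        elif s in _POST_STATE:
            cost_active.add(s)
            util_active.add(_POST_STATE[s])
        else:
            cost_active.add(s)
            if s in util_vocab:
                util_active.add(s)
    if "end_stage_renal_disease" in baseline or "kidney_transplant" in baseline:
        nm = modality or (
            "kidney_transplant" if "kidney_transplant" in baseline else "hemodialysis"
        )
        cost_active.add(nm)
        util_active.add(nm)
    return cost_active, util_active, has_depression


def value_trajectory(
    traj: Trajectory,
    cost_table: Optional[CostTable] = None,
    utility_table: Optional[UtilityTable] = None,
    include_indirect: bool = False,
    disability: Optional[DisabilityDurations] = None,
    salary: Optional[SalaryTable] = None,
) -> Tuple[List[Dict[str, float]], List[float]]:
    """Per-cycle (category -> MXN) cost dicts and utility weights for one
    patient.  With ``include_indirect`` the cost dicts gain an ``indirect``
    category (human-capital productivity loss)."""
    if cost_table is None:
        cost_table = CostTable.default()
    if utility_table is None:
        utility_table = UtilityTable.default()
    if include_indirect:
        disability = disability or DisabilityDurations()
        salary = salary or SalaryTable()
    util_vocab = utility_table.vocabulary

    patient = traj.patient
    cost_active, util_active, has_depression = _baseline_sets(traj, util_vocab)

    onsets_by_cycle: Dict[int, List[str]] = {}
    for name, t in traj.onset_cycles.items():
        onsets_by_cycle.setdefault(t, []).append(name)

    run = traj.run
    i = traj.i
    n_cycles = traj.n_cycles
    death_cycle = traj.death_cycle
    fatal = traj.fatal_complication
    modality = traj.esrd_modality

    costs: List[Dict[str, float]] = []
    utils: List[float] = []
    for t in range(n_cycles):
        incident_cost: Set[str] = set()
        util_events: Dict[str, int] = {}
        pending_post: List[str] = []
        for name in onsets_by_cycle.get(t, ()):  # engine order not relevant
            if name == "end_stage_renal_disease":
                nm = modality or "hemodialysis"
                incident_cost.add(nm)
                if nm in util_vocab:
                    util_active.add(nm)
            elif name in _POST_STATE:
                incident_cost.add(name)
                util_events[name] = util_events.get(name, 0) + 1
                pending_post.append(_POST_STATE[name])
            elif name in _CLEARS:
                for cleared in _CLEARS[name]:
                    cost_active.discard(cleared)
                    util_active.discard(cleared)
                incident_cost.add(name)
                if name in util_vocab:
                    util_active.add(name)
            else:
                incident_cost.add(name)
                if name in util_vocab:
                    util_active.add(name)

        acute: Dict[str, int] = {}
        for a, ev in enumerate(ACUTE_EVENTS):
            c = int(run.acute_counts[i, t, a])
            if c:
                acute[ev] = c
                if ev in _ACUTE_UTILITY:
                    uname = _ACUTE_UTILITY[ev]
                    util_events[uname] = util_events.get(uname, 0) + c

        snap = CycleSnapshot(
            arm=traj.arm,
            incident_states=incident_cost,
            prevalent_states=set(cost_active),
            acute_events=acute,
            medications=set(patient.medications),
            has_depression=has_depression,
            fatal_complication=fatal if death_cycle == t else None,
        )
        cyc_cost = annual_direct_cost(snap, table=cost_table)
        if include_indirect:
            days = 0.0
            for name in incident_cost:
                days += disability.get(name)
            for name in cost_active:
                days += disability.get(f"{name}_annual")
            for ev, c in acute.items():
                days += disability.get(ev) * c
            ind = indirect_cost(patient.age + t, patient.sex, days, salary)
            cyc_cost["indirect"] = ind
            cyc_cost["total"] += ind
        costs.append(cyc_cost)
        utils.append(annual_utility(util_active, util_events, utility_table))

        cost_active |= incident_cost
        util_active.update(pending_post)
    return costs, utils


def value_run(
    run: ArmRun,
    cost_table: Optional[CostTable] = None,
    utility_table: Optional[UtilityTable] = None,
    include_indirect: bool = False,
    disability: Optional[DisabilityDurations] = None,
    salary: Optional[SalaryTable] = None,
):
    """Cost and utility streams for every patient of an arm."""
    cost_table = cost_table or CostTable.default()
    utility_table = utility_table or UtilityTable.default()
    all_costs, all_utils = [], []
    for traj in run:
        c, u = value_trajectory(
            traj, cost_table, utility_table, include_indirect, disability, salary
        )
        all_costs.append(c)
        all_utils.append(u)
    return all_costs, all_utils
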