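"""Health-state utilities and QALY accumulation.

Combination rules:

* a patient's base utility in a cycle is the *minimum* of the per-condition
  utilities over all active conditions (0.785, the no-complication baseline,
  when none are active);
* one-off disutilities of this cycle's events (severe/minor hypoglycaemia
  always; incident myocardial infarction, stroke and amputation in their
  event cycle) are subtracted on top;
* conditions with a post-event health-state value (post-MI 0.73, post-stroke
  0.621, kidney transplant 0.762, post-amputation 0.505) contribute that
  value to the minimum; chronic conditions contribute baseline + decrement
  (e.g. neuropathy 0.785 - 0.084 = 0.701);
* the result is clamped below at 0 so per-cycle QALYs are never negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Union

import yaml

__all__ = [
    "UtilityTable",
    "condition_utility",
    "annual_utility",
    "qaly_increment",
]


@dataclass
class UtilityTable:
    """Utility catalogue (see packaged ``data/utility_table.yaml``)."""

    baseline_no_complication: float = 0.785
    one_off: Dict[str, float] = field(default_factory=dict)  # negative values
    chronic_decrement: Dict[str, float] = field(default_factory=dict)
    post_event_states: Dict[str, float] = field(default_factory=dict)
    zero_disutility: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_no_complication <= 1.0:
            raise ValueError("baseline utility must be in (0, 1]")
        for group in (self.one_off, self.chronic_decrement):
            for k, v in group.items():
                if v > 0:
                    raise ValueError(f"decrement {k!r} must be <= 0 as stored")
        for k, v in self.post_event_states.items():
            if v > self.baseline_no_complication:
                raise ValueError(f"post-event state {k!r} exceeds baseline utility")

    @property
    def vocabulary(self) -> Set[str]:
        return (
            set(self.chronic_decrement)
            | set(self.post_event_states)
            | set(self.zero_disutility)
        )

    @classmethod
    def from_dict(cls, data: Mapping) -> "UtilityTable":
        return cls(
            baseline_no_complication=float(data["baseline_no_complication"]),
            one_off={k: float(v) for k, v in data.get("one_off", {}).items()},
            chronic_decrement={
                k: float(v) for k, v in data.get("chronic_decrement", {}).items()
            },
            post_event_states={
                k: float(v) for k, v in data.get("post_event_states", {}).items()
            },
            zero_disutility=list(data.get("zero_disutility", [])),
        )

    @classmethod
    def from_yaml(cls, path) -> "UtilityTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "UtilityTable":
        from importlib.resources import files

        with files("t1dcea.data").joinpath("utility_table.yaml").open() as fh:
            return cls.from_dict(yaml.safe_load(fh))


def condition_utility(condition: str, table: Optional[UtilityTable] = None) -> float:
    """Utility of a single active condition.

    Post-event states return their health-state value; chronic states return
    baseline plus their (negative) decrement; explicitly zero-disutility
    states return the baseline.
    """
    if table is None:
        table = UtilityTable.default()
    if condition in table.post_event_states:
        return table.post_event_states[condition]
    if condition in table.chronic_decrement:
        return table.baseline_no_complication + table.chronic_decrement[condition]
    if condition in table.zero_disutility:
        return table.baseline_no_complication
    raise KeyError(f"unknown condition {condition!r}")


def annual_utility(
    active_conditions: Iterable[str],
    events_this_cycle: Union[Iterable[str], Mapping[str, int]] = (),
    table: Optional[UtilityTable] = None,
) -> float:
    """Utility weight for one cycle: minimum rule over active conditions,
    minus the one-off disutilities of this cycle's events, clamped to [0, 1].

    ``events_this_cycle`` may be a list (possibly with repeats) or an
    event -> count mapping; events without a one-off entry contribute nothing.
    """
    if table is None:
        table = UtilityTable.default()
    base = table.baseline_no_complication
    values = [condition_utility(c, table) for c in active_conditions]
    u = min(values) if values else base
    if isinstance(events_this_cycle, Mapping):
        items = events_this_cycle.items()
    else:
        counted: Dict[str, int] = {}
        for ev in events_this_cycle:
            counted[ev] = counted.get(ev, 0) + 1
        items = counted.items()
    for ev, count in items:
        u += table.one_off.get(ev, 0.0) * count
    return min(max(u, 0.0), 1.0)


def qaly_increment(utility: float, years: float = 1.0, discount_factor: float = 1.0) -> float:
    """Discounted QALY contribution of a cycle."""
    if not 0.0 <= utility <= 1.0:
        raise ValueError(f"utility {utility} outside [0, 1]")
    return utility * years * discount_factor
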