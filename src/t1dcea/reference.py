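"""Headline figures reported by the published IMSS CSII-vs-MDI evaluation.

These are *inputs for arithmetic-identity checks and reporting comparisons*
(e.g. verifying that the printed incremental cost and incremental QALYs imply
the printed ICER), never outputs of this package's own simulation — the
absolute lifetime totals depend on proprietary disease-model internals this
package deliberately does not claim to reproduce.
"""

from __future__ import annotations

#: Base-case (direct costs, 5%/5% discounting, lifetime horizon) results.
BASE_CASE = {
    "csii_total_cost_mxn": 1_404_173.0,
    "mdi_total_cost_mxn": 1_110_573.0,
    "delta_cost_mxn": 293_600.0,
    "csii_qalys": 7.052,
    "mdi_qalys": 6.438,
    "delta_qalys": 0.614,
    "delta_life_years": 0.696,
    "icer_per_qaly_mxn": 478_020.0,
    "icer_per_lyg_mxn": 434_577.0,
}

#: Cohort-level inputs of the intervention-effect regressions.
EFFECT_INPUTS = {
    "baseline_hba1c": 9.2,  # percent
    "mdi_severe_hypo_rate": 22.4,  # events / 100 patient-years
    "mean_age": 32.3,  # years
}

#: Printed event-year cost of myocardial infarction (2016 MXN), the anchor of
#: the subsequent-year (event/9) derivation rule.
MI_EVENT_YEAR_COST_MXN = 267_057.59
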