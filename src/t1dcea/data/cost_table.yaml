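# Unit costs in 2016 Mexican pesos (MXN), IMSS single-payer perspective.
# Values transcribed from the published cost table of the IMSS CSII-vs-MDI
# evaluation (DRG-based episode costs inflated 2014->2016 at 0.0865;
# subsequent-year maintenance rows are one ninth of the event-year cost).
# event_year: cost in the year of the event/onset
# subsequent_year: cost in each later year the state remains active

exchange_rate_mxn_per_usd: 18.390
drg_inflation_2014_2016: 0.0865

therapy:
  csii_annual: 53568.00   # pump amortized over its 4-year warranty + supplies + insulin
  mdi_annual: 22884.97

events:
  myocardial_infarction: {event_year: 267057.59, subsequent_year: 29673.07}
  angina: {event_year: 108136.66, subsequent_year: 12015.18}
  congestive_heart_failure: {event_year: 155593.67, subsequent_year: 17288.19}
  stroke: {event_year: 41540.56, subsequent_year: 4615.62}
  stroke_death_within_30_days: {event_year: 41104.86, subsequent_year: 0.0}
  peripheral_vascular_disease: {event_year: 83605.69, subsequent_year: 9289.52}
  hemodialysis: {event_year: 434803.79, subsequent_year: 351393.12}
  peritoneal_dialysis: {event_year: 301440.53, subsequent_year: 212620.35}
  kidney_transplant: {event_year: 425899.73, subsequent_year: 27466.00}
  background_retinopathy: {event_year: 0.0, subsequent_year: 0.0}
  # proliferative retinopathy costed as laser treatment at onset
  proliferative_retinopathy: {event_year: 24097.72, subsequent_year: 0.0}
  macular_edema: {event_year: 0.0, subsequent_year: 0.0}
  cataract: {event_year: 35895.20, subsequent_year: 957.00}
  severe_visual_loss: {event_year: 52652.36, subsequent_year: 957.00}
  neuropathy: {event_year: 63586.97, subsequent_year: 37982.45}
  uninfected_ulcer: {event_year: 32703.13, subsequent_year: 32703.13}
  infected_ulcer: {event_year: 45010.25, subsequent_year: 45010.25}
  healed_ulcer: {event_year: 957.00, subsequent_year: 957.00}
  # amputation prosthesis is not covered -> no subsequent-year cost
  amputation: {event_year: 157824.66, subsequent_year: 0.0}
  gangrene: {event_year: 118143.63, subsequent_year: 0.0}
  microalbuminuria: {event_year: 0.0, subsequent_year: 0.0}
  gross_proteinuria: {event_year: 0.0, subsequent_year: 0.0}

acute:   # per event
  severe_hypo: 37000.53
  minor_hypo: 990.00
  ketoacidosis: 37000.53
  lactic_acidosis: 37000.53
  edema: 990.00            # onset visit; follow-up consultations below
  edema_follow_up: 957.00

medications_monthly:
  statins: 50.59
  aspirin: 0.09
  ace_inhibitors: 7.30
  antidepressants: 981.78

screening_annual:   # per procedure, applied annually to alive patients
  microalbuminuria: 97.00
  gross_proteinuria: 97.00
  retinopathy: 316.00
  depression: 957.00
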