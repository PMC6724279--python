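# Health-state utilities and event disutilities (standard published T1D/T2D
# utility catalogue).  baseline: utility with no complications.
# one_off: decrement applied once, in the cycle the event occurs (stored as
#   negative values, added to the running utility).
# chronic_decrement: decrement applied every cycle the state is active, via
#   the minimum rule (condition utility = baseline + decrement).
# post_event_states: absolute health-state value for patients after the event.
# zero_disutility: states explicitly carrying no decrement.

baseline_no_complication: 0.785

one_off:
  myocardial_infarction: -0.055
  stroke: -0.164
  amputation: -0.28
  major_hypo: -0.047
  minor_hypo: -0.014

chronic_decrement:
  angina: -0.09
  congestive_heart_failure: -0.108
  peripheral_vascular_disease: -0.061
  gross_proteinuria: -0.048
  hemodialysis: -0.164
  peritoneal_dialysis: -0.204
  background_retinopathy: -0.04
  background_retinopathy_wrongly_treated: -0.04
  proliferative_retinopathy: -0.07   # laser treated or not, same decrement
  macular_edema: -0.04
  severe_visual_loss: -0.074
  cataract: -0.016
  neuropathy: -0.084
  uninfected_ulcer: -0.17   # "active ulcer"
  infected_ulcer: -0.17

post_event_states:
  post_myocardial_infarction: 0.73
  post_stroke: 0.621
  kidney_transplant: 0.762
  post_amputation: 0.505

zero_disutility:
  - microalbuminuria
  - healed_ulcer
  - post_edema
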