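# Synthetic default disease-progression parameters.
#
# IMPORTANT: these hazards, relative risks, fatality probabilities and the
# Gompertz mortality coefficients are illustrative values of plausible
# magnitude chosen for this package.  They are NOT the transition
# probabilities of any proprietary diabetes model and NOT taken from the
# published evaluation this package re-implements (those internals are not
# public).  Replace them with your own calibrated inputs for substantive use.
#
# hazard: annual onset hazard at the reference HbA1c (events/year)
# rr_per_pct_hba1c: relative risk per +1 percentage point HbA1c
# predecessor: state required before onset is possible
# fatality_prob: probability the incident event is fatal within its cycle

reference_hba1c: 7.0

mortality:
  type: gompertz
  a_male: 0.0022
  a_female: 0.0018
  b: 0.075

# events per 100 patient-years, identical across arms (severe hypoglycaemia
# is arm-specific and comes from the treatment-effects module instead)
acute_event_rates:
  minor_hypo: 0.0
  ketoacidosis: 0.0
  lactic_acidosis: 0.0
  edema: 0.0

complications:
  - name: background_retinopathy
    hazard: 0.045
    rr_per_pct_hba1c: 1.12
  - name: proliferative_retinopathy
    hazard: 0.025
    rr_per_pct_hba1c: 1.12
    predecessor: background_retinopathy
  - name: macular_edema
    hazard: 0.012
    rr_per_pct_hba1c: 1.10
    predecessor: background_retinopathy
  - name: severe_visual_loss
    hazard: 0.010
    rr_per_pct_hba1c: 1.08
    predecessor: proliferative_retinopathy
  - name: cataract
    hazard: 0.010
    rr_per_pct_hba1c: 1.05
  - name: microalbuminuria
    hazard: 0.040
    rr_per_pct_hba1c: 1.12
  - name: gross_proteinuria
    hazard: 0.022
    rr_per_pct_hba1c: 1.10
    predecessor: microalbuminuria
  - name: end_stage_renal_disease
    hazard: 0.012
    rr_per_pct_hba1c: 1.08
    predecessor: gross_proteinuria
    modality_split:
      hemodialysis: 0.5
      peritoneal_dialysis: 0.3
      kidney_transplant: 0.2
  - name: neuropathy
    hazard: 0.030
    rr_per_pct_hba1c: 1.10
  - name: uninfected_ulcer
    hazard: 0.015
    rr_per_pct_hba1c: 1.08
    predecessor: neuropathy
  - name: infected_ulcer
    hazard: 0.020
    rr_per_pct_hba1c: 1.05
    predecessor: uninfected_ulcer
  - name: healed_ulcer
    hazard: 0.30
    rr_per_pct_hba1c: 1.0
    predecessor: uninfected_ulcer
  - name: gangrene
    hazard: 0.015
    rr_per_pct_hba1c: 1.05
    predecessor: infected_ulcer
    fatality_prob: 0.05
  - name: amputation
    hazard: 0.006
    rr_per_pct_hba1c: 1.08
    predecessor: neuropathy
    fatality_prob: 0.05
  - name: angina
    hazard: 0.008
    rr_per_pct_hba1c: 1.06
  - name: myocardial_infarction
    hazard: 0.007
    rr_per_pct_hba1c: 1.08
    fatality_prob: 0.30
  - name: congestive_heart_failure
    hazard: 0.005
    rr_per_pct_hba1c: 1.06
    fatality_prob: 0.10
  - name: stroke
    hazard: 0.006
    rr_per_pct_hba1c: 1.06
    fatality_prob: 0.25
  - name: peripheral_vascular_disease
    hazard: 0.009
    rr_per_pct_hba1c: 1.07
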