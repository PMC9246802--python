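# Population translation parameters: yearly senescence rates past the
# onset age and mild-AD fold changes relative to age-matched elderly.
ad_fold_changes:
  bbb_paracellular_factor: 4.4
  bbb_sa_factor: 1.1123
  bcsfb_paracellular_factor: 1.0
  brain_ph_shift: 0.0
  brain_volume_factor: 0.95
  cbf_norm_factor: 0.85
  ecf_bulk_flow_factor: 0.85
  ecf_fraction_factor: 1.4
  extraventricular_factor: 1.21
  lumbar_csf_ph_shift: 0.018
  phospholipid_factor: 0.9
  transporter_factors: {}
  ventricle_factor: 1.39
aging_rates:
  bbb_sa_decline: 10.0
  brain_shrinkage_rate: 0.401
  cm_expansion_rate: 1.09
  compounding: true
  ecf_bulk_flow_decline: 33.0
  ecf_fraction_change: -16.0
  icf_ph_drift: -0.001
  onset_age: 60.0
  phospholipid_decline_60_80: 10.0
  phospholipid_decline_80_100: 8.0
  sas_expansion_rate: 0.78
  ventricle_expansion_rate: 3.45
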