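# Reference cognitively-healthy-young (CHY) CNS physiology.
# Units: mL, mL/min, cm2, g/mL, pH. Overridable field by field.
physiology:
  age: 35.0
  brain_density: 1.045
  brain_volume: 1400.0
  f_bcsfb_lv: 0.5
  f_ecf: 0.2
  f_icf: 0.8
  f_paracellular_bbb: 1.0
  f_paracellular_bcsfb: 1.0
  f_phospholipid: 0.05
  label: CHY
  ph_csf: 7.3
  ph_ecf: 7.3
  ph_icf: 7.0
  ph_lyso: 5.0
  ph_plasma: 7.4
  provenance:
    brain_density: literature-default
    brain_volume: literature-default
    f_bcsfb_lv: package-default
    f_ecf: literature-primary
    f_icf: literature-primary
    f_paracellular_bbb: reference = 1
    f_paracellular_bcsfb: reference = 1
    f_phospholipid: literature-primary
    ph_csf: standard physiology
    ph_ecf: standard physiology
    ph_icf: standard physiology
    ph_lyso: standard physiology
    ph_plasma: standard physiology
    q_cbf_norm: literature-default
    q_cbf_total: 'derived: q_cbf_norm x brain_mass / 100'
    q_csf: literature-default
    q_ecf_bulk: literature-default
    sa_bbb: literature-default
    sa_bcsfb: literature-default
    transporter_activity: reference = 1
    v_cm: literature-default
    v_lv: literature-default
    v_lysosome: literature-default
    v_microvasc: literature-default
    v_sas: literature-default
    v_tfv: literature-default
  q_cbf_norm: 48.0
  q_cbf_total: 702.24
  q_csf: 0.35
  q_ecf_bulk: 0.2
  sa_bbb: 150000.0
  sa_bcsfb: 75000.0
  transporter_activity:
    bcrp: 1.0
    cht: 1.0
    octn1: 1.0
    pgp: 1.0
  v_cm: 7.5
  v_lv: 22.5
  v_lysosome: 11.2
  v_microvasc: 35.0
  v_sas: 175.0
  v_tfv: 7.5
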