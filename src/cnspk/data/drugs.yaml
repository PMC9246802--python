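# Shipped drug registry: physicochemical and biological parameters.
# mw g/mol; IC50 ng/mL (unbound scale); Kpuu dimensionless.
drugs:
  donepezil:
    fu_b: 0.107
    fu_p: 0.07
    ic50: 0.57
    kpuu_bbb: 0.482
    kpuu_bbb_species: rat
    kpuu_lumbar: 1.8
    kpuu_lv: 1.8
    logp: 4.14
    mw: 379.49
    pka_acid: 17.02
    pka_base: 8.62
    species_scaling:
      bcrp: 1.1
      pgp: 0.22
    target: acetylcholinesterase
    transporter_substrate:
      bcrp: true
      cht: true
      pgp: true
  galantamine:
    fu_b: 0.333
    fu_p: 0.83
    ic50: 55.0
    kpuu_bbb: 0.826
    kpuu_bbb_species: human
    kpuu_lumbar: 1.2
    kpuu_lv: 1.2
    logp: 1.16
    mw: 287.35
    pka_acid: 14.81
    pka_base: 8.58
    species_scaling: {}
    target: acetylcholinesterase
    transporter_substrate: {}
  memantine:
    fu_b: 0.071
    fu_p: 0.55
    ic50: 109.0
    kpuu_bbb: 2.0
    kpuu_bbb_species: rat
    kpuu_lumbar: 0.89
    kpuu_lv: 0.89
    logp: 3.31
    mw: 179.3
    pka_acid: null
    pka_base: 10.7
    species_scaling: {}
    target: NMDA receptor
    transporter_substrate:
      octn1: true
  rivastigmine:
    fu_b: 0.376
    fu_p: 0.6
    ic50: 857.2
    ic50_secondary: 9.3
    kpuu_bbb: 0.733
    kpuu_bbb_species: human
    kpuu_lumbar: 0.663
    kpuu_lv: 0.663
    logp: 2.45
    mw: 250.3
    pka_acid: null
    pka_base: 8.89
    species_scaling: {}
    target: acetylcholinesterase
    target_secondary: butyrylcholinesterase
    transporter_substrate:
      cht: true
  semagacestat:
    fu_b: 0.413
    fu_p: 0.382
    ic50: 5.4
    kpuu_bbb: 0.55
    kpuu_bbb_species: human
    kpuu_lumbar: 0.55
    kpuu_lv: 0.55
    logp: 0.44
    mw: 361.4
    pka_acid: 11.91
    pka_base: -3.7
    species_scaling: {}
    target: gamma-secretase
    transporter_substrate: {}
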