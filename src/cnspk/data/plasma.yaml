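# Empirical unbound plasma PK parameters (mL, mL/min, 1/min)
# and clinical dosing regimens (mg, min).
plasma:
  donepezil:
    cl_cen: 2048.0
    ka: 0.022
    v_cen: 391000.0
  galantamine:
    cl_cen: 192.0
    ka: 0.051
    n_compartments: 2
    q_cen_per1: 510.0
    v_cen: 157000.0
    v_per1: 59000.0
  memantine:
    cl_cen: 228.0
    ka: 0.005
    v_cen: 194000.0
  rivastigmine:
    cl_cen: 3333.0
    f_rel: 1.4
    ka: 0.052
    v_cen: 236000.0
  semagacestat:
    cl_cen: 846.0
    ka: 0.012
    v_cen: 71700.0
regimen:
  donepezil:
    dose: 10.0
    interval: 1440.0
  galantamine:
    dose: 10.0
    interval: 720.0
  memantine:
    dose: 20.0
    interval: 1440.0
  rivastigmine:
    dose: 6.0
    interval: 720.0
  semagacestat:
    dose: 140.0
    interval: 1440.0
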