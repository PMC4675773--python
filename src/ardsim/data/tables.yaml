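# In-print configuration tables shipped as package fixtures.
# table1: nominal values and allowed ranges of the per-compartment
#   mechanical parameters; table2: three ARDS patient datasets (data and
#   published model-fit columns); table3: ventilation settings of the
#   formula-based strategies.
table1:
  TOP:
    nominal: 30.0
    range: [5.0, 60.0]
    units: cmH2O
  S:
    nominal: 0.05
    range: [0.005, 0.5]
    units: cmH2O/ml^2
  P_ext:
    nominal: 28.8
    range: [-20.0, 28.8]
    units: cmH2O
table2:
  A:
    CO: 13.0
    FiO2: 0.8
    Hb: 112.0
    PVR: 152.0
    C_dyn: 37.0
    DC: 0.33
    RR: 12.5
    data: {PaO2: 201.0, PvO2: 45.83, PvCO2: 46.73, shunt: 30.0}
    model: {PaO2: 203.1, PvO2: 47.68, PvCO2: 43.34, shunt: 30.8}
  B:
    CO: 10.1
    FiO2: 1.0
    Hb: 79.0
    PVR: 152.1
    C_dyn: 31.0
    DC: 0.33
    RR: 12.5
    data: {PaO2: 165.75, PvO2: 42.0, PvCO2: 43.5, shunt: 33.5}
    model: {PaO2: 166.29, PvO2: 41.51, PvCO2: 43.61, shunt: 34.7}
  C:
    CO: 3.9
    FiO2: 1.0
    Hb: 98.0
    PVR: 151.9
    C_dyn: 33.0
    DC: 0.33
    RR: 12.5
    data: {PaO2: 56.32, PvO2: 24.83, PvCO2: 39.3, shunt: 34.7}
    model: {PaO2: 55.59, PvO2: 25.66, PvCO2: 39.79, shunt: 35.21}
table3:
  RR: [16.0, 24.0, 32.0, 40.0, 48.0]
  V_T: [497.5, 385.0, 328.75, 295.0, 272.5]
  V_D_anat: [160.0, 160.0, 160.0, 160.0, 160.0]
  M_Valv: [5400.0, 5400.0, 5400.0, 5400.0, 5400.0]
  DC_strategy1: [0.33, 0.33, 0.33, 0.33, 0.33]
  DC_strategy2: [0.40, 0.46, 0.52, 0.58, 0.65]
  F_insp_strategy1: [404.04, 466.67, 531.31, 595.96, 660.61]
  F_insp_strategy2: [337.0, 337.0, 337.0, 337.0, 337.0]
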