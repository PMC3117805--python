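walls:
  LVF:
    E_ES: 3.5
    V_d: 1.0
    P_0: 2.0
    lam: 0.025
    V_0: 1.0
  RVF:
    E_ES: 0.34
    V_d: 3.0
    P_0: 1.0
    lam: 0.01
    V_0: 3.0
  SPT:
    E_ES: 40.0
    V_d: 0.0
    P_0: 1.11
    lam: 0.05
    V_0: 0.0
  LA:
    E_ES: 2.5
    V_d: 7.0
    P_0: 2.0
    lam: 0.1
    V_0: 40.0
  RA:
    E_ES: 0.34
    V_d: 3.0
    P_0: 1.0
    lam: 0.1
    V_0: 30.0
activations:
  LVF:
    wall_id: LVF
    normalization_scale: 0.9994146990987652
    terms:
    - A: 0.282
      B: 0.043
      C: 0.11
    - A: 0.075
      B: 0.03
      C: 0.165
    - A: 0.384
      B: 0.05
      C: 0.22
    - A: 0.205
      B: 0.04
      C: 0.3
    - A: 0.37
      B: 0.08
      C: 0.35
    - A: 0.516
      B: 0.06
      C: 0.395
    - A: 0.15
      B: 0.04
      C: 0.405
  RVF:
    wall_id: RVF
    normalization_scale: 0.9994146990987652
    terms:
    - A: 0.282
      B: 0.043
      C: 0.11
    - A: 0.075
      B: 0.03
      C: 0.165
    - A: 0.384
      B: 0.05
      C: 0.22
    - A: 0.205
      B: 0.04
      C: 0.3
    - A: 0.37
      B: 0.08
      C: 0.35
    - A: 0.516
      B: 0.06
      C: 0.395
    - A: 0.15
      B: 0.04
      C: 0.405
  SPT:
    wall_id: SPT
    normalization_scale: 0.9994146990987652
    terms:
    - A: 0.282
      B: 0.043
      C: 0.11
    - A: 0.075
      B: 0.03
      C: 0.165
    - A: 0.384
      B: 0.05
      C: 0.22
    - A: 0.205
      B: 0.04
      C: 0.3
    - A: 0.37
      B: 0.08
      C: 0.35
    - A: 0.516
      B: 0.06
      C: 0.395
    - A: 0.15
      B: 0.04
      C: 0.405
pericardium:
  P_PERI0: 0.5
  lam_PERI: 0.005
  V_PERI0: 200.0
  V_PERI_FLUID: 6.0
compartments:
  AO_p:
    C: 2.4
    V_un: 20.0
    thoracic: true
  AO_d:
    C: 0.43
    V_un: 120.0
    thoracic: false
  SA:
    C: 0.092
    V_un: 200.0
    thoracic: false
  SA_d:
    C: 0.069
    V_un: 150.0
    thoracic: false
  SC:
    C: 0.8
    V_un: 250.0
    thoracic: false
  SVL:
    C: 0.6
    V_un: 300.0
    thoracic: false
  SV:
    C: 37.5
    V_un: 2550.0
    thoracic: false
  VC:
    C: 4.0
    V_un: 100.0
    thoracic: true
  PA_p:
    C: 0.69
    V_un: 7.8420000000000005
    thoracic: true
  PA_d:
    C: 0.64
    V_un: 9.580000000000002
    thoracic: true
  PA:
    C: 6.0
    V_un: 97.9
    thoracic: true
  PC:
    C: 2.1
    V_un: 66.55000000000001
    thoracic: true
  PV:
    C: 7.3
    V_un: 132.73000000000002
    thoracic: true
valves:
  mitral: 0.007
  tricuspid: 0.0028
  aortic: 0.005
  pulmonic: 0.002
resistances:
  R_AO_d: 0.015
  R_SA: 0.015
  R_SA_d: 0.35
  R_SC: 0.4
  R_SVL: 0.2
  R_SV: 0.2
  R_VC: 0.026
  R_RA: 0.01
  R_PA_d: 0.002
  R_PA: 0.01
  R_PC: 0.08
  R_PV: 0.008
  R_LA: 0.01
  R_PS: 4.0
  R_COR: 35.0
  R_CRB: 16.0
  R_TAO: 0.051
  R_TAO_d: 0.0125
  R_TPA: 0.035
inertances:
  L_AO_p: 0.0055
  L_AO_d: 0.0031
  L_PA: 8.0e-05
neural:
  baro_slope: 0.004246727930938457
  baro_intercept: 0.0006711222500697714
  limb_slopes:
    F_HRv: 1.3846153846153846
    F_HRs: -2.1923076923076903
    F_con: -2.653846153846154
    F_vaso: -3.1538461538461506
  limb_intercepts:
    F_HRv: -0.028076923076922947
    F_HRs: 1.181538461538461
    F_con: 1.4892307692307694
    F_vaso: 1.8392307692307681
  limb_tau:
    F_HRv: 0.5
    F_HRs: 2.0
    F_con: 2.0
    F_vaso: 2.0
  hr_h0: -14.917647058825036
  hr_hs: 151.7647058823544
  hr_hv: -50.588235294119684
  tau_msap: 2.0
  k_alpha: 2.0
  F_con_ref: 0.4
  k_vaso_R: 12.0
  k_vaso_V: 500.0
  F_vaso_ref: 0.5
  K_f: 1.2
total_blood_volume: 5000.0
pleural_mode: fixed_minus5
la_width: 0.053
ra_width: 0.092
atrial_offset: 0.06
la_amplitude: 1.0
ra_amplitude: 1.0
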