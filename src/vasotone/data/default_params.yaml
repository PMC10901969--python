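# Default parameter file: fitted coefficients for rat middle cerebral
# arteries (vessels group 1).  Group 2 differs only in R_o_prime_cm (0.0126).
chemical:
  P_max_mmHg: 150.0
  n_XBmax: 0.55
  tau: [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
  edges:
    chi0: {B0: 0.131, K: 15.470, n: 0.464}      # pressure -> Ca2+
    chi1: {B0: 0.181, K: 6413.033, n: 3.083}    # pressure -> ROCK
    chi2: {B0: 0.000, K: 0.926, n: 0.558}       # pressure -> pHSP27 (PKC)
    chi3: {B0: 0.000, K: 0.512, n: 1.325}       # ROCK -> pMLCP
    chi4: {B0: 0.419, K: 0.219, n: 15.825}      # ROCK -> pCofilin
    chi5: {B0: 0.000, K: 0.423, n: 521.545}     # Ca2+ -> MLCK drive on LC20
    chi6: {B0: 0.020, K: 0.332, n: 10.680}      # pMLCP -| MLCP activity
    chi7: {B0: 0.187, K: 0.440, n: 88.701}      # pCofilin -| G-actin
    chi8: {B0: 0.142, K: 4401.162, n: 1.408}    # pHSP27 -| G-actin
mechanical:
  N_CU: 10                       # contractile units in series (literature order)
  L_SMC_cm: 0.01
  L_m_cm: 3.0e-5
  u_PS_cm: 1.424e-6
  kXB_over_dm_dyne_cm2: 8.166777e+6
  u_fs_opt: 1.490e-2
  s_f0_cm: 5.870e-7
  k_ACmax_dyne_cm: 10.04
  n_AC: 4.156
  K_AC: 10.201
  N_CF_cm2: 2.44e+10
  beta_c: 1.0
geometry:
  R_o_prime_cm: 0.0110
  h_w: 0.367
  lambda_z: 1.364
  k_omega: 1.373
passive:
  c0_dyne_cm2: 9.1633e+4
  c1_dyne_cm2: 3.15e+4
  c2: 0.646
  phi_deg: 0.0
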