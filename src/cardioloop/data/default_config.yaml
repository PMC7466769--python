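version: 1
electrophysiology:
  Ca_Vleak:
    base_value: 1.0
    units: x published
    multiplier: 1.0
  Ca_Vmaxup:
    base_value: 1.0
    units: x published
    multiplier: 1.0
  g_CaL:
    base_value: 1.0
    units: x published
    multiplier: 1.0
  g_to:
    base_value: 1.0
    units: x published
    multiplier: 1.0
  g_Kr:
    base_value: 1.0
    units: x published
    multiplier: 1.0
  g_Ks:
    base_value: 1.0
    units: x published
    multiplier: 1.0
sarcomere:
  k_on:
    base_value: 200000.0
    units: mM^-1 s^-1
    multiplier: 1.0
  k_off:
    base_value: 200.0
    units: s^-1
    multiplier: 1.0
  k_coop:
    base_value: 26.0
    units: dimensionless
    multiplier: 1.0
  k_1:
    base_value: 1.0
    units: s^-1
    multiplier: 1.0
  k_2:
    base_value: 17.5
    units: s^-1
    multiplier: 1.0
  k_3:
    base_value: 105.0
    units: s^-1 nm^-1
    multiplier: 1.0
  k_4_0:
    base_value: 120.0
    units: s^-1
    multiplier: 1.0
  k_4_1:
    base_value: 0.065
    units: s^-1 nm^-4
    multiplier: 1.0
  k_cb:
    base_value: 0.001
    units: N m^-1
    multiplier: 1.0
  x_ps:
    base_value: 4.5
    units: nm
    multiplier: 1.0
  N_0:
    base_value: 2.0e+17
    units: m^-2
    multiplier: 1.0
  sigma:
    base_value: 1150.0
    units: N m^-2
    multiplier: 1.0
  L:
    base_value: 70.0
    units: nm
    multiplier: 1.0
  L_slack:
    base_value: 900.0
    units: nm
    multiplier: 1.0
  k_force:
    base_value: 0.00022
    units: m^2 N^-1
    multiplier: 1.0
  n_overlap:
    base_value: 1.0
    units: dimensionless
    multiplier: 1.0
  w_ascending:
    base_value: 120.0
    units: nm
    multiplier: 1.0
  hsl_full_overlap:
    base_value: 1000.0
    units: nm
    multiplier: 1.0
  hsl_desc_start:
    base_value: 1100.0
    units: nm
    multiplier: 1.0
  hsl_desc_end:
    base_value: 1500.0
    units: nm
    multiplier: 1.0
  hsl_zero_overlap:
    base_value: 730.0
    units: nm
    multiplier: 1.0
ventricle:
  V_slack:
    base_value: 0.1
    units: L
    multiplier: 1.0
  W_volume:
    base_value: 0.1
    units: L
    multiplier: 1.0
  V_residual:
    base_value: 0.008
    units: L
    multiplier: 1.0
circulation:
  C_aorta:
    base_value: 0.00135
    units: L mmHg^-1
    multiplier: 1.0
  C_arteries:
    base_value: 0.0009
    units: L mmHg^-1
    multiplier: 1.0
  C_arterioles:
    base_value: 0.0015
    units: L mmHg^-1
    multiplier: 1.0
  C_capillaries:
    base_value: 0.005
    units: L mmHg^-1
    multiplier: 1.0
  C_veins:
    base_value: 0.45
    units: L mmHg^-1
    multiplier: 1.0
  R_aortic_valve:
    base_value: 15.0
    units: mmHg s L^-1
    multiplier: 1.0
  R_arteries:
    base_value: 25.0
    units: mmHg s L^-1
    multiplier: 1.0
  R_arterioles:
    base_value: 1100.0
    units: mmHg s L^-1
    multiplier: 1.0
  R_capillaries:
    base_value: 350.0
    units: mmHg s L^-1
    multiplier: 1.0
  R_veins:
    base_value: 80.0
    units: mmHg s L^-1
    multiplier: 1.0
  R_venous_return:
    base_value: 30.0
    units: mmHg s L^-1
    multiplier: 1.0
  V_total:
    base_value: 5.0
    units: L
    multiplier: 1.0
protocol:
  n_beats: 17
  rate_hz: 1.0
  stim_amplitude: -52.0
  stim_duration_ms: 3.0
  initial_fill_fraction: 1.5
  withdrawal_fraction: 0.6
  withdrawal_start_beat: 10
  withdrawal_end_beat: 15
numerics:
  dt_ms: 1.0
  hemo_substeps: 8
  sarcomere_substeps: 1
  ep_prepace_beats: 1000
  strain_x_min: -10.0
  strain_x_max: 10.0
  strain_dx: 0.5
output:
  directory: out
  cadence_ms: 1.0
sweeps:
  parameters:
  - k_1
  - k_2
  - k_3
  - k_4_0
  - k_cb
  - k_force
  - k_on
  - k_off
  - k_coop
  - sigma
  - L
  - L_slack
  - Ca_Vleak
  - Ca_Vmaxup
  - g_CaL
  - g_to
  - g_Kr
  - g_Ks
  - V_slack
  - W_volume
  - C_veins
  - C_aorta
  - R_arterioles
  - V_total
  multipliers:
  - 0.1
  - 0.178
  - 0.316
  - 0.562
  - 1.0
  - 1.78
  - 3.16
  - 5.62
  - 10.0
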