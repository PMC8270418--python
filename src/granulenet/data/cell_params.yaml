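# Single-cell model parameters for the granular-layer network, version 1.
# Units: capacitance pF, conductance nS, voltage mV, time ms.
version: 1
common:
  tau_ahpx_ms: 1.0      # AHP resource decay
  t_ref_ms: 2.0         # absolute refractory period after the spike plateau
  v_plateau_mv: 40.0    # clamped membrane potential during the spike plateau
noise:
  sigma_n_ns: 0.12      # stationary scale of the Ornstein-Uhlenbeck conductance
  tau_n_ms: 1000.0      # OU correlation time
  v_e_mv: 0.0           # reversal of the noise current (excitatory)
gc:
  model: gc             # nonlinear-leak integrate-and-fire
  c_m_pf: 4.9
  g_l_ns: 1.5
  e_l_mv: -90.0
  v_t_mean_mv: -49.0
  v_t_sd_mv: 2.45
  v_rest_mv: -65.0
  g_ahp_ns: 1.0
  e_k_mv: -90.0
  tau_ahp_ms: 3.0
  tau_dur_ms: 0.6
  leak_shape_mv: 5.0    # voltage scale of the exp(-(V-E_L)/5) leak nonlinearity
goc:
  model: goc            # exponential integrate-and-fire with gap junctions
  c_m_pf: 20.0
  g_l_ns: 1.0
  e_l_mv: -50.0
  v_t_mean_mv: -45.0
  v_t_sd_mv: 2.25
  v_rest_mv: -50.0
  g_ahp_ns: 4.0
  e_k_mv: -100.0
  tau_ahp_ms: 20.0
  tau_dur_ms: 1.0
  delta_t_mv: 3.0       # EIF spike-initiation slope factor
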