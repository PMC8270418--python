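# Receptor kinetics and short-term-plasticity parameters per projection, version 1.
# g_mult scales the projection weight mean W (nS); alpha in 1/ms; taus in ms.
# Rows without tau_rec/tau_fac are always static (R = 1, u = U frozen).
version: 1
nmda_half_mv: 84.0
nmda_slope_mv: 38.0
reversals:
  ampa_mv: 0.0
  nmda_mv: 0.0
  gaba_mv: -75.0
projections:
  mf_gc:
    - {name: AMPA_fast, g_mult: 1.0,  alpha: 3.0,  tau_rise: 0.3, tau_decay: 0.8,
       U: 0.5,  tau_rec: 12.0,  tau_fac: 12.0,  receptor: ampa}
    - {name: AMPA_slow, g_mult: 2.0,  alpha: 0.3,  tau_rise: 0.5, tau_decay: 5.0,
       U: 0.5,  tau_rec: 12.0,  tau_fac: 12.0,  receptor: ampa}
    - {name: NMDA,      g_mult: 2.4,  alpha: 0.35, tau_rise: 8.0, tau_decay: 30.0,
       U: 0.05, tau_rec: null,  tau_fac: null,  receptor: nmda}
  mf_goc:
    - {name: AMPA_fast, g_mult: 1.0,  alpha: 3.0,  tau_rise: 0.3, tau_decay: 0.8,
       U: 0.5,  tau_rec: null,  tau_fac: null,  receptor: ampa}
    - {name: AMPA_slow, g_mult: 2.0,  alpha: 0.3,  tau_rise: 0.5, tau_decay: 5.0,
       U: 0.5,  tau_rec: null,  tau_fac: null,  receptor: ampa}
  gc_goc:
    - {name: AMPA_fast, g_mult: 1.0,  alpha: 3.0,  tau_rise: 0.3, tau_decay: 0.8,
       U: 0.5,  tau_rec: null,  tau_fac: null,  receptor: ampa}
  goc_gc:
    - {name: GABA_fast, g_mult: 1.0,  alpha: 3.0,  tau_rise: 1.0, tau_decay: 5.0,
       U: 0.5,  tau_rec: 400.0, tau_fac: 20.0,  receptor: gaba}
    - {name: GABA_slow, g_mult: 0.15, alpha: 0.35, tau_rise: 5.0, tau_decay: 100.0,
       U: 0.05, tau_rec: 20.0,  tau_fac: 400.0, receptor: gaba}
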