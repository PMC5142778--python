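{
  "n_excitatory": 4000,
  "n_inhibitory": 1000,
  "tau_m_e": 15.0,
  "tau_m_i": 10.0,
  "bias_range_e": [1.1, 1.2],
  "bias_range_i": [1.0, 1.05],
  "v_threshold": 1.0,
  "v_reset": 0.0,
  "refractory": 5.0,
  "tau_rise": 1.0,
  "tau_decay_e": 3.0,
  "tau_decay_i": 2.0,
  "J_EE": 0.024,
  "J_EI": -0.045,
  "J_IE": 0.014,
  "J_II": -0.057,
  "p_EE": 0.2,
  "p_EI": 0.5,
  "p_IE": 0.5,
  "p_II": 0.5,
  "n_clusters": 50,
  "cluster_size": 80,
  "p_in_EE": 0.4854,
  "p_out_EE": 0.1942,
  "J_in_EE": 0.0456,
  "J_out_EE": 0.024,
  "dt": 0.05,
  "burn_in": 2.0
}
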