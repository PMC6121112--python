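{
  "g_fi": 3.0,
  "g_so": 0.02,
  "g_so_rest": 0.12,
  "g_si": 0.0223,
  "tau_v_plus": 3.33,
  "tau_v1_minus": 1000.0,
  "tau_v2_minus": 19.6,
  "tau_w_plus": 667.0,
  "tau_w_minus": 11.0,
  "u_c": 0.13,
  "u_si": 0.85,
  "u_v": 0.055,
  "k": 10.0,
  "c_m": 1.0
}
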