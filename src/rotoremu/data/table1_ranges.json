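{
  "g_fi": 0.3,
  "g_so": 0.2,
  "g_so_rest": 0.3,
  "g_si": 0.2,
  "tau_v_plus": 0.5,
  "tau_v1_minus": 0.5,
  "tau_v2_minus": 0.5,
  "tau_w_plus": 0.5,
  "tau_w_minus": 0.5
}
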