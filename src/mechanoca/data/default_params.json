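{
  "v_pump": 0.121185,
  "k_pump": 0.6,
  "v_cru": 1.12458,
  "k_cru": 1.680609,
  "m_cru": 4.0,
  "k_h": 0.591495,
  "tau_h": 9.238245,
  "v_ncx": 0.154596,
  "k_ncx": 1.0,
  "q_ncx": 0.497268,
  "k_na": 0.008799,
  "k_leak": null,
  "k_leak_na": null
}
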