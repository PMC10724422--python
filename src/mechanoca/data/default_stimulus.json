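{
  "t_on": 12.3,
  "duration": 2.812967,
  "intensity": 0.16293,
  "na_coupled": true
}
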