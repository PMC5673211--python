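{
 "densities_g_cm3": {
  "water": 1.0,
  "adipose": 0.95,
  "glandular": 1.04,
  "skin": 1.09,
  "connective": 1.12,
  "pmma": 1.19,
  "ptfe": 2.2,
  "aluminum": 2.699
 }
}
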