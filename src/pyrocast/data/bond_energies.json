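{
  "_comment": "Mean homolytic bond enthalpies, kJ/mol, keyed by 'El-El:order' with elements sorted alphabetically. Used by the baseline reaction scorer and the additive activation-energy estimator.",
  "H-H:1": 436,
  "C-H:1": 413,
  "C-C:1": 347,
  "C-C:2": 614,
  "C-C:3": 839,
  "C-O:1": 358,
  "C-O:2": 745,
  "C-O:3": 1072,
  "H-O:1": 464,
  "O-O:1": 146,
  "O-O:2": 495,
  "C-N:1": 305,
  "C-N:2": 615,
  "C-N:3": 891,
  "H-N:1": 391,
  "N-N:1": 163,
  "N-N:2": 418,
  "N-N:3": 941,
  "N-O:1": 201,
  "N-O:2": 607,
  "C-S:1": 259,
  "H-S:1": 363,
  "S-S:1": 266,
  "O-S:2": 522
}
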