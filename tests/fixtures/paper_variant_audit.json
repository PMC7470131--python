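{
  "description": "Deviation of the printed erfc release series from the exact plane-sheet solution on 50 log-spaced tau in [1e-4, 2] (paper variant minus exact; 50/200 series terms).",
  "max_abs_deviation": 0.5874809530074719,
  "tau_at_max": 0.5948031522982123,
  "sign_at_max": -1,
  "n_tau": 50
}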