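{
  "huJ591-like": {
    "label": "huJ591-like",
    "amp_fast": 15.0,
    "rate_fast": -0.07,
    "amp_slow": 25.0,
    "rate_slow": -0.012,
    "provenance": "Synthetic parameter set emulating the serum clearance of 89Zr-huJ591 in metastatic prostate cancer patients (fastest clearance of the bundled profiles). Fitted coefficients of the source serum curve are not publicly tabulated; these values were chosen once to give a realistic t=0 concentration (40 %IA/L ~ injected activity in ~2.5 L plasma), distribution half-life ~9.9 h, terminal half-life ~58 h, and to reproduce the published ordering of plasma AUC and the reported sparse-sampling Ki bias range (down to about -16% with a 24 h sample included)."
  },
  "trastuzumab-like": {
    "label": "trastuzumab-like",
    "amp_fast": 16.0,
    "rate_fast": -0.07,
    "amp_slow": 26.0,
    "rate_slow": -0.0075,
    "provenance": "Synthetic parameter set emulating the serum clearance of 89Zr-trastuzumab in esophagogastric cancer patients (intermediate clearance). t=0 concentration 42 %IA/L, distribution half-life ~9.9 h, terminal half-life ~92 h; reproduces the published intermediate plasma AUC and a sparse-sampling Ki bias range down to about -10% with a 24 h sample included."
  },
  "pertuzumab-like": {
    "label": "pertuzumab-like",
    "amp_fast": 14.0,
    "rate_fast": -0.06,
    "amp_slow": 30.0,
    "rate_slow": -0.0045,
    "provenance": "Synthetic parameter set emulating the serum clearance of 89Zr-pertuzumab in breast cancer patients (slowest clearance, largest plasma AUC of the bundled profiles). t=0 concentration 44 %IA/L, distribution half-life ~11.6 h, terminal half-life ~154 h; reproduces the published largest plasma AUC and the smallest sparse-sampling Ki bias (about -1.5% to -5% with a 24 h sample included)."
  }
}
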