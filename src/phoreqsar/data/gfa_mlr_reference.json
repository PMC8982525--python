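{
  "name": "GFA-MLR reference equation",
  "response": "log(1/IC50)",
  "intercept": -1.667,
  "coefficients": {
    "Hypo(5-R6-08)": 0.12,
    "Hypo(1-R2-08)": 0.129,
    "LYS_191_HZ2^CD": -0.276,
    "VAL_324_HB^LD": -0.22,
    "Num_Rings5": 0.433,
    "PMI_x": -0.002,
    "Shadow_XYfrac": -2.65
  }
}
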