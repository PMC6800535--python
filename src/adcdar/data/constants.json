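{
  "antibody": {
    "name": "trastuzumab",
    "mw_formula_Da": 145423.0,
    "mw_measured_Da": 147836.9
  },
  "drug": {
    "name": "DM1",
    "mw_Da": 738.29,
    "lambda_max_nm": 252.0
  },
  "linkers": [
    {"name": "SMCC", "spacer_arm_A": 8.3, "mw_Da": 334.32, "leaving_group_Da": 115.0},
    {"name": "SM(PEG)2", "spacer_arm_A": 17.6, "mw_Da": 425.39, "leaving_group_Da": 115.0},
    {"name": "SM(PEG)12", "spacer_arm_A": 53.4, "mw_Da": 865.92, "leaving_group_Da": 115.0}
  ],
  "extinctions": {
    "eAb252": 74311.0,
    "eAb280": 209409.0,
    "eD252": 25600.0,
    "eD280": 4410.0
  },
  "path_cm": 0.56
}
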