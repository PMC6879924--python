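{
  "description": "Age-specific reference blood-pressure statistics (mean, sd) of healthy adults used by the plausibility filter: aortic and brachial SBP/DBP/MAP/PP [mmHg] and pulse-pressure amplification [ratio]. A subject is plausible when every quantity lies within mean +/- 2.575 sd (the 99% confidence band).",
  "ages": [25, 35, 45, 55, 65, 75],
  "quantities": {
    "aortic_SBP":  {"mean": [100.1, 104.6, 110.1, 111.9, 113.6, 115.1], "sd": [8.0, 8.4, 8.4, 8.7, 8.7, 9.4]},
    "aortic_DBP":  {"mean": [74.7, 77.3, 78.9, 77.4, 74.8, 71.7],      "sd": [5.7, 6.0, 6.1, 6.2, 6.6, 7.2]},
    "aortic_MAP":  {"mean": [89.2, 92.8, 96.3, 96.2, 95.4, 94.2],      "sd": [6.2, 6.1, 6.1, 6.0, 5.9, 5.8]},
    "aortic_PP":   {"mean": [25.4, 27.3, 31.3, 34.5, 38.9, 43.4],      "sd": [7.0, 8.3, 8.5, 9.4, 10.2, 12.3]},
    "brachial_SBP": {"mean": [112.3, 115.9, 120.4, 120.6, 120.2, 120.1], "sd": [8.7, 9.1, 8.6, 8.5, 8.3, 8.7]},
    "brachial_DBP": {"mean": [72.0, 74.5, 76.3, 75.0, 72.3, 69.5],      "sd": [5.6, 6.1, 6.2, 6.3, 6.6, 7.1]},
    "brachial_MAP": {"mean": [88.9, 92.5, 96.1, 96.1, 95.2, 94.0],      "sd": [6.1, 6.3, 6.1, 6.0, 5.9, 5.8]},
    "brachial_PP":  {"mean": [40.3, 41.5, 44.1, 45.6, 47.9, 50.6],      "sd": [8.2, 9.2, 9.1, 9.6, 9.8, 11.5]},
    "PP_amp":      {"mean": [1.62, 1.56, 1.44, 1.35, 1.26, 1.19],      "sd": [0.15, 0.16, 0.13, 0.13, 0.11, 0.10]}
  }
}
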