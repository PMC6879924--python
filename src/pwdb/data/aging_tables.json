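{
  "description": "Per-decade anchors (means and SDs) of the cardiovascular input parameters of the virtual-population model, compiled from population studies of healthy adults. SDs are intersubject (normal variation at fixed age). A three-point +/-1 SD grid has sample SD = sd*sqrt(2/3); cohort columns of the source tables were rescaled accordingly where the prescribed SD was not stated directly.",
  "ages": [25, 35, 45, 55, 65, 75],
  "parameters": {
    "HR": {
      "units": "beats/min", "interp": "pchip",
      "mean": [73.0, 76.3, 77.0, 77.0, 76.3, 74.4],
      "sd": [11.0, 11.0, 11.0, 11.0, 11.0, 11.0]
    },
    "SV": {
      "units": "ml", "interp": "linear",
      "mean": [66.8, 64.1, 61.3, 58.7, 55.8, 53.6],
      "sd": [16.0, 15.3, 14.2, 13.6, 12.7, 12.0]
    },
    "LVET": {
      "units": "ms", "interp": "linear",
      "mean": [282.0, 282.0, 282.0, 282.0, 282.0, 282.0],
      "sd": [24.0, 24.0, 24.0, 24.0, 24.0, 24.0]
    },
    "PFT": {
      "units": "ms", "interp": "linear",
      "mean": [79.0, 79.0, 79.0, 79.0, 79.0, 79.0],
      "sd": [11.0, 11.0, 11.0, 11.0, 11.0, 11.0]
    },
    "RFV": {
      "units": "ml", "interp": "linear",
      "mean": [0.73, 0.73, 0.73, 0.73, 0.73, 0.73],
      "sd": [0.63, 0.63, 0.63, 0.63, 0.63, 0.63]
    },
    "MAP": {
      "units": "mmHg", "interp_mean": "cubic", "interp_sd": "linear",
      "mean": [89.2, 92.8, 96.3, 96.2, 95.4, 94.2],
      "sd": [7.6, 7.5, 7.5, 7.3, 7.2, 7.1]
    },
    "DBP": {
      "units": "mmHg", "interp": "linear",
      "mean": [74.7, 77.3, 78.9, 77.4, 74.8, 71.7],
      "sd": [7.0, 7.4, 7.5, 7.6, 8.1, 8.8]
    },
    "proximal_aortic_length": {
      "units": "mm", "interp": "linear",
      "mean": [80.0, 86.4, 92.8, 99.2, 105.6, 112.0],
      "sd": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
    },
    "diameter_ascending": {
      "units": "mm", "interp": "linear",
      "mean": [36.7, 37.8, 39.0, 40.2, 41.4, 42.6],
      "sd": [3.2, 3.3, 3.4, 3.6, 3.7, 3.7]
    },
    "diameter_desc_thoracic": {
      "units": "mm", "interp": "linear",
      "mean": [24.4, 25.2, 26.0, 26.8, 27.6, 28.3],
      "sd": [2.1, 2.2, 2.3, 2.3, 2.4, 2.4]
    },
    "diameter_abdominal": {
      "units": "mm", "interp": "linear",
      "mean": [14.5, 15.0, 15.4, 15.9, 16.3, 16.8],
      "sd": [1.2, 1.3, 1.3, 1.3, 1.5, 1.5]
    },
    "diameter_carotid": {
      "units": "mm", "interp": "linear",
      "mean": [6.1, 6.3, 6.5, 6.7, 6.85, 7.0],
      "sd": [0.5, 0.5, 0.5, 0.5, 0.5, 0.5]
    },
    "pwv_aortic": {
      "units": "m/s", "interp": "linear",
      "mean": [5.9, 6.5, 7.3, 8.0, 8.9, 9.7],
      "sd_plus": [0.73, 0.98, 1.1, 1.35, 1.59, 1.96],
      "sd_minus": [0.73, 0.98, 1.1, 1.35, 1.59, 1.96]
    },
    "pwv_arm": {
      "units": "m/s", "interp": "linear",
      "mean": [8.9, 9.5, 10.4, 11.1, 12.0, 12.8],
      "sd_plus": [0.73, 0.98, 0.98, 1.22, 1.59, 1.96],
      "sd_minus": [0.73, 0.98, 0.98, 1.22, 1.59, 1.96]
    },
    "pwv_leg": {
      "units": "m/s", "interp": "linear",
      "mean": [8.7, 9.2, 10.1, 10.7, 11.6, 12.4],
      "sd_plus": [1.1, 1.35, 0.98, 1.22, 1.47, 1.84],
      "sd_minus": [1.1, 1.35, 0.98, 1.22, 1.47, 1.84]
    },
    "pvc": {
      "units": "1e-9 m^3/Pa", "interp": "linear",
      "mean": [40.1, 35.5, 31.0, 26.4, 21.9, 17.3],
      "sd": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
    }
  },
  "varied": ["HR", "SV", "LVET", "diameter", "PWV", "MAP"],
  "pwv_map_sensitivity": 0.10
}
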