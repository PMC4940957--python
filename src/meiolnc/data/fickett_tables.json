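{
  "version": 1,
  "comment": "TESTCODE position-asymmetry and base-content lookup tables with their weights (Fickett 1982).",
  "position_parameter": [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0],
  "position_probability": {
    "A": [0.51, 0.55, 0.57, 0.52, 0.48, 0.58, 0.57, 0.54, 0.50, 0.36],
    "C": [0.29, 0.44, 0.55, 0.49, 0.52, 0.60, 0.60, 0.56, 0.51, 0.38],
    "G": [0.62, 0.67, 0.74, 0.65, 0.61, 0.62, 0.66, 0.63, 0.48, 0.29],
    "T": [0.51, 0.60, 0.69, 0.64, 0.53, 0.54, 0.44, 0.51, 0.40, 0.28]
  },
  "position_weight": {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33},
  "content_parameter": [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.17, 0.0],
  "content_probability": {
    "A": [0.40, 0.55, 0.58, 0.58, 0.52, 0.48, 0.45, 0.45, 0.38],
    "C": [0.50, 0.63, 0.59, 0.50, 0.41, 0.30, 0.24, 0.30, 0.23],
    "G": [0.21, 0.40, 0.47, 0.46, 0.52, 0.58, 0.54, 0.52, 0.30],
    "T": [0.30, 0.49, 0.56, 0.53, 0.48, 0.48, 0.34, 0.20, 0.45]
  },
  "content_weight": {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
}
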