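{
  "galega": {
    "slope_pct_per_microlumen": 5.62,
    "intercept_pct": 22.9,
    "r_squared": 0.9999,
    "n_points": 3,
    "flux_range_lm": [2.15e-06, 3.57e-06],
    "provenance": "published galega germination-flux calibration (double-scarified seeds)"
  },
  "clover": {
    "slope_pct_per_microlumen": 1.59,
    "intercept_pct": 5.72,
    "r_squared": 0.9919,
    "n_points": 3,
    "flux_range_lm": [3.15e-06, 9.46e-06],
    "provenance": "published clover germination-flux calibration (double-scarified seeds)"
  },
  "alfalfa": {
    "slope_pct_per_microlumen": 3.66,
    "intercept_pct": 28.2,
    "r_squared": 0.9315,
    "n_points": 3,
    "flux_range_lm": [3.56e-06, 1.38e-05],
    "provenance": "published alfalfa germination-flux calibration (double-scarified seeds)"
  }
}
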