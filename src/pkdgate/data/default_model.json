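{
  "constants": {
    "g_max": 1.0,
    "e_rev": 11.64,
    "temperature": 298.15
  },
  "channels": {
    "WT": {
      "v_half": 138.3,
      "slope_inv_mv": 0.0249,
      "basal": 0.02,
      "amplitude": 0.98,
      "tau_depol": {
        "form": "logistic",
        "amplitude_ms": 20.7,
        "rate_per_mv": 0.025,
        "center_mv": 145.0
      },
      "tau_hyperpol": {
        "offset_ms": 0.0,
        "amplitude_ms": 10.9,
        "rate_per_mv": 0.001,
        "shift_mv": 0.0
      },
      "rectification": {
        "gamma_in": 161.9,
        "gamma_out": 102.4,
        "e_rev": 11.64,
        "transition_width": 15.0,
        "inward_range": [
          -100.0,
          40.0
        ],
        "outward_range": [
          40.0,
          140.0
        ]
      }
    },
    "K452Q": {
      "v_half": 295.0,
      "slope_inv_mv": 0.0234,
      "basal": 0.02,
      "amplitude": 0.98,
      "tau_depol": {
        "form": "logistic-literal",
        "amplitude_ms": 60.6,
        "rate_per_mv": 0.008,
        "center_mv": 70.0
      },
      "tau_hyperpol": {
        "offset_ms": 0.0,
        "amplitude_ms": 1.7,
        "rate_per_mv": 0.008,
        "shift_mv": 69.1
      },
      "rectification": {
        "gamma_in": 117.3,
        "gamma_out": 137.8,
        "e_rev": 11.64,
        "transition_width": 15.0,
        "inward_range": [
          -100.0,
          40.0
        ],
        "outward_range": [
          40.0,
          140.0
        ]
      }
    },
    "K455Q": {
      "v_half": 280.0,
      "slope_inv_mv": 0.0233,
      "basal": 0.02,
      "amplitude": 0.98,
      "tau_depol": {
        "form": "logistic",
        "amplitude_ms": 54.6,
        "rate_per_mv": 0.0065,
        "center_mv": 25.0
      },
      "tau_hyperpol": {
        "offset_ms": 0.0,
        "amplitude_ms": 1.6,
        "rate_per_mv": 0.008,
        "shift_mv": 80.75
      },
      "rectification": {
        "gamma_in": 125.5,
        "gamma_out": 77.0,
        "e_rev": 11.64,
        "transition_width": 15.0,
        "inward_range": [
          -100.0,
          40.0
        ],
        "outward_range": [
          40.0,
          140.0
        ]
      }
    },
    "K461Q": {
      "v_half": 182.7,
      "slope_inv_mv": 0.0217,
      "basal": 0.02,
      "amplitude": 0.98,
      "tau_depol": {
        "form": "logistic",
        "amplitude_ms": 10.12,
        "rate_per_mv": 0.0237,
        "center_mv": 125.2
      },
      "tau_hyperpol": {
        "offset_ms": 1.33,
        "amplitude_ms": 0.16,
        "rate_per_mv": 0.014,
        "shift_mv": 0.0
      },
      "rectification": {
        "gamma_in": 184.3,
        "gamma_out": 85.9,
        "e_rev": 11.64,
        "transition_width": 15.0,
        "inward_range": [
          -100.0,
          40.0
        ],
        "outward_range": [
          40.0,
          140.0
        ]
      }
    }
  }
}
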