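{
  "partial_scores": {
    "aflibercept_folfiri": {
      "os": 83.9,
      "hrqol": 15.0,
      "pfs": 90.3,
      "g4ae": -117.9,
      "atc_l4": 100.0,
      "phase3": 50.0,
      "mkt_auth": 100.0,
      "posology": 0.0,
      "med_costs": 7.0
    },
    "cetuximab": {
      "os": 44.4,
      "hrqol": 15.0,
      "pfs": 51.4,
      "g4ae": 50.0,
      "atc_l4": 100.0,
      "phase3": 66.7,
      "mkt_auth": 30.0,
      "posology": 37.5,
      "med_costs": 50.0
    },
    "panitumumab": {
      "os": 48.9,
      "hrqol": 15.0,
      "pfs": 55.6,
      "g4ae": 30.0,
      "atc_l4": 0.0,
      "phase3": 19.4,
      "mkt_auth": 0.0,
      "posology": 100.0,
      "med_costs": 78.9
    }
  },
  "wpv": {
    "cetuximab": 45.7,
    "panitumumab": 42.3,
    "aflibercept_folfiri": 14.4
  },
  "ranking": [
    "cetuximab",
    "panitumumab",
    "aflibercept_folfiri"
  ],
  "weights_printed_integer": {
    "os": 29,
    "hrqol": 13,
    "pfs": 5,
    "g4ae": 23,
    "atc_l4": 6,
    "phase3": 2,
    "mkt_auth": 3,
    "posology": 7,
    "med_costs": 12
  },
  "cluster_weights_printed": {
    "therapeutic": 47,
    "safety": 23,
    "socioeconomic": 12
  },
  "headline_two_weight_sum": 52.1,
  "cost_per_value_unit": {
    "cetuximab": 394,
    "panitumumab": 638,
    "aflibercept_folfiri": 2046
  },
  "sensitivity": [
    {
      "pair": [
        "cetuximab",
        "panitumumab"
      ],
      "thresholds": {
        "os": 59.8,
        "pfs": 47.7,
        "g4ae": 7.5,
        "atc_l4": 2.5,
        "posology": 11.8,
        "med_costs": 21.0
      }
    },
    {
      "pair": [
        "cetuximab",
        "aflibercept_folfiri"
      ],
      "thresholds": {
        "os": 60.3,
        "pfs": 47.3,
        "g4ae": 5.6,
        "mkt_auth": 33.3
      }
    },
    {
      "pair": [
        "panitumumab",
        "aflibercept_folfiri"
      ],
      "thresholds": {
        "os": 60.4,
        "pfs": 47.2,
        "g4ae": 5.4,
        "atc_l4": 26.4,
        "phase3": 49.0,
        "mkt_auth": 24.6
      }
    }
  ],
  "most_sensitive_relative_changes": {
    "posology": 0.69,
    "med_costs": 0.81
  },
  "grade4_contribution_aflibercept": -27.4,
  "nice_icer_documentation": {
    "aflibercept_folfiri": 51000,
    "cetuximab": 90000,
    "panitumumab": 110000
  }
}
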