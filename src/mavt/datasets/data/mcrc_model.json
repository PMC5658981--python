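{
  "schema": "mavt-model/1",
  "tree": {
    "root": {
      "id": "overall_value",
      "name": "Overall value of mCRC second-line treatment"
    },
    "clusters": [
      {
        "id": "therapeutic",
        "name": "Therapeutic impact",
        "attributes": [
          "os",
          "hrqol",
          "pfs"
        ]
      },
      {
        "id": "safety",
        "name": "Safety profile",
        "attributes": [
          "g4ae"
        ]
      },
      {
        "id": "innovation",
        "name": "Innovation level",
        "attributes": [
          "atc_l4",
          "phase3",
          "mkt_auth",
          "posology"
        ]
      },
      {
        "id": "socioeconomic",
        "name": "Socioeconomic impact",
        "attributes": [
          "med_costs"
        ]
      }
    ]
  },
  "attributes": [
    {
      "id": "atc_l4",
      "name": "ATC L4",
      "cluster": "innovation",
      "metric": "relative market entrance in the ATC chemical class",
      "units": "",
      "kind": "binary",
      "direction": "increasing",
      "lower_ref": "2nd or later",
      "higher_ref": "1st",
      "levels": [
        "2nd or later",
        "1st"
      ]
    },
    {
      "id": "g4ae",
      "name": "Grade 4 AEs",
      "cluster": "safety",
      "metric": "patients with a Grade 4 adverse event",
      "units": "% of patients",
      "kind": "continuous",
      "direction": "decreasing",
      "minimum": 0.0,
      "maximum": 21.0,
      "lower_ref": 10.0,
      "higher_ref": 0.0
    },
    {
      "id": "hrqol",
      "name": "HRQoL",
      "cluster": "therapeutic",
      "metric": "health-related quality of life (EQ-5D utility)",
      "units": "utility",
      "kind": "continuous",
      "direction": "increasing",
      "minimum": 0.75,
      "maximum": 0.9,
      "lower_ref": 0.75,
      "higher_ref": 0.9
    },
    {
      "id": "med_costs",
      "name": "Medical costs impact",
      "cluster": "socioeconomic",
      "metric": "direct medical costs excluding drug purchase",
      "units": "GBP",
      "kind": "continuous",
      "direction": "decreasing",
      "minimum": 0.0,
      "maximum": 7086.0,
      "lower_ref": 7086.0,
      "higher_ref": 0.0
    },
    {
      "id": "mkt_auth",
      "name": "Marketing authorisation",
      "cluster": "innovation",
      "metric": "new indications with marketing authorisation",
      "units": "count",
      "kind": "continuous",
      "direction": "increasing",
      "minimum": 0.0,
      "maximum": 3.0,
      "lower_ref": 0.0,
      "higher_ref": 3.0
    },
    {
      "id": "os",
      "name": "Overall survival",
      "cluster": "therapeutic",
      "metric": "median time from randomisation to death",
      "units": "months",
      "kind": "continuous",
      "direction": "increasing",
      "minimum": 6.2,
      "maximum": 14.9,
      "lower_ref": 6.2,
      "higher_ref": 14.9
    },
    {
      "id": "pfs",
      "name": "Progression free survival",
      "cluster": "therapeutic",
      "metric": "median time without disease progression",
      "units": "months",
      "kind": "continuous",
      "direction": "increasing",
      "minimum": 1.9,
      "maximum": 7.6,
      "lower_ref": 1.9,
      "higher_ref": 7.6
    },
    {
      "id": "phase3",
      "name": "Phase 3",
      "cluster": "innovation",
      "metric": "new indications in Phase 3 trials",
      "units": "count",
      "kind": "continuous",
      "direction": "increasing",
      "minimum": 0.0,
      "maximum": 21.0,
      "lower_ref": 0.0,
      "higher_ref": 21.0
    },
    {
      "id": "posology",
      "name": "Posology",
      "cluster": "innovation",
      "metric": "administration duration and dose frequency",
      "units": "",
      "kind": "ordinal",
      "direction": "increasing",
      "lower_ref": "Many hours, every 2 weeks",
      "higher_ref": "≤1 hour, every 2 weeks",
      "levels": [
        "Many hours, every 2 weeks",
        "1 hour, every week",
        "≤1 hour, every 2 weeks"
      ]
    }
  ],
  "value_functions": [
    {
      "attribute": "atc_l4",
      "levels": {
        "1st": 100.0,
        "2nd or later": 0.0
      }
    },
    {
      "attribute": "g4ae",
      "anchors": [
        [
          0.0,
          100.0
        ],
        [
          5.0,
          50.0
        ],
        [
          7.0,
          30.0
        ],
        [
          10.0,
          0.0
        ],
        [
          21.0,
          -117.9
        ]
      ]
    },
    {
      "attribute": "hrqol",
      "anchors": [
        [
          0.75,
          0.0
        ],
        [
          0.78,
          15.0
        ],
        [
          0.9,
          100.0
        ]
      ]
    },
    {
      "attribute": "med_costs",
      "anchors": [
        [
          0.0,
          100.0
        ],
        [
          1940.0,
          78.9
        ],
        [
          4589.0,
          50.0
        ],
        [
          6738.0,
          7.0
        ],
        [
          7086.0,
          0.0
        ]
      ]
    },
    {
      "attribute": "mkt_auth",
      "anchors": [
        [
          0.0,
          0.0
        ],
        [
          1.0,
          30.0
        ],
        [
          3.0,
          100.0
        ]
      ]
    },
    {
      "attribute": "os",
      "anchors": [
        [
          6.2,
          0.0
        ],
        [
          10.0,
          44.4
        ],
        [
          10.4,
          48.9
        ],
        [
          13.5,
          83.9
        ],
        [
          14.9,
          100.0
        ]
      ]
    },
    {
      "attribute": "pfs",
      "anchors": [
        [
          1.9,
          0.0
        ],
        [
          4.1,
          51.4
        ],
        [
          4.4,
          55.6
        ],
        [
          6.9,
          90.3
        ],
        [
          7.6,
          100.0
        ]
      ]
    },
    {
      "attribute": "phase3",
      "anchors": [
        [
          0.0,
          0.0
        ],
        [
          7.0,
          19.4
        ],
        [
          18.0,
          50.0
        ],
        [
          19.0,
          66.7
        ],
        [
          21.0,
          100.0
        ]
      ]
    },
    {
      "attribute": "posology",
      "levels": {
        "1 hour, every week": 37.5,
        "Many hours, every 2 weeks": 0.0,
        "≤1 hour, every 2 weeks": 100.0
      }
    }
  ],
  "weights": {
    "atc_l4": 5.8,
    "g4ae": 23.3,
    "hrqol": 12.8,
    "med_costs": 11.6,
    "mkt_auth": 3.5,
    "os": 28.9,
    "pfs": 4.8,
    "phase3": 2.3,
    "posology": 7.0
  }
}
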