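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
          "pfs",
          "orr"
        ]
      },
      {
        "id": "safety",
        "name": "Safety profile",
        "attributes": [
          "g3ae",
          "g4ae",
          "contraindications"
        ]
      },
      {
        "id": "innovation",
        "name": "Innovation level",
        "attributes": [
          "atc_l1",
          "atc_l2",
          "atc_l3",
          "atc_l4",
          "atc_l5",
          "phase1",
          "phase2",
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
      "id": "atc_l1",
      "name": "ATC Level 1",
      "cluster": "innovation",
      "metric": "",
      "units": "",
      "kind": "ordinal",
      "direction": "increasing",
      "lower_ref": "5th",
      "higher_ref": "4th",
      "levels": [
        "5th",
        "4th",
        "3rd",
        "2nd",
        "1st"
      ]
    },
    {
      "id": "atc_l2",
      "name": "ATC Level 2",
      "cluster": "innovation",
      "metric": "",
      "units": "",
      "kind": "ordinal",
      "direction": "increasing",
      "lower_ref": "5th",
      "higher_ref": "4th",
      "levels": [
        "5th",
        "4th",
        "3rd",
        "2nd",
        "1st"
      ]
    },
    {
      "id": "atc_l3",
      "name": "ATC Level 3",
      "cluster": "innovation",
      "metric": "",
      "units": "",
      "kind": "ordinal",
      "direction": "increasing",
      "lower_ref": "5th",
      "higher_ref": "3rd",
      "levels": [
        "5th",
        "4th",
        "3rd",
        "2nd",
        "1st"
      ]
    },
    {
      "id": "atc_l4",
      "name": "ATC Level 4",
      "cluster": "innovation",
      "metric": "",
      "units": "",
      "kind": "ordinal",
      "direction": "increasing",
      "lower_ref": "5th",
      "higher_ref": "1st",
      "levels": [
        "5th",
        "4th",
        "3rd",
        "2nd",
        "1st"
      ]
    },
    {
      "id": "atc_l5",
      "name": "ATC Level 5",
      "cluster": "innovation",
      "metric": "",
      "units": "",
      "kind": "ordinal",
      "direction": "increasing",
      "lower_ref": "5th",
      "higher_ref": "1st",
      "levels": [
        "5th",
        "4th",
        "3rd",
        "2nd",
        "1st"
      ]
    },
    {
      "id": "contraindications",
      "name": "Contra-indications",
      "cluster": "safety",
      "metric": "",
      "units": "",
      "kind": "binary",
      "direction": "increasing",
      "lower_ref": "Lower expected benefit and higher expected risk",
      "higher_ref": "Lower expected benefit",
      "levels": [
        "Lower expected benefit and higher expected risk",
        "Lower expected benefit"
      ]
    },
    {
      "id": "g3ae",
      "name": "Grade 3 AEs",
      "cluster": "safety",
      "metric": "",
      "units": "% of patients",
      "kind": "continuous",
      "direction": "decreasing",
      "minimum": 0.0,
      "maximum": 100.0,
      "lower_ref": 68.0,
      "higher_ref": 32.0
    },
    {
      "id": "g4ae",
      "name": "Grade 4 AEs",
      "cluster": "safety",
      "metric": "",
      "units": "% of patients",
      "kind": "continuous",
      "direction": "decreasing",
      "minimum": 0.0,
      "maximum": 100.0,
      "lower_ref": 24.0,
      "higher_ref": 10.0
    },
    {
      "id": "hrqol",
      "name": "HRQoL",
      "cluster": "therapeutic",
      "metric": "",
      "units": "utility",
      "kind": "continuous",
      "direction": "increasing",
      "minimum": 0.0,
      "maximum": 1.0,
      "lower_ref": 0.6,
      "higher_ref": 0.75
    },
    {
      "id": "med_costs",
      "name": "Medical costs impact",
      "cluster": "socioeconomic",
      "metric": "",
      "units": "GBP",
      "kind": "continuous",
      "direction": "decreasing",
      "minimum": 0.0,
      "maximum": 7086.0,
      "lower_ref": 7086.0,
      "higher_ref": 4589.0
    },
    {
      "id": "mkt_auth",
      "name": "Marketing authorisation",
      "cluster": "innovation",
      "metric": "",
      "units": "count",
      "kind": "continuous",
      "direction": "increasing",
      "minimum": 0.0,
      "lower_ref": 0.0,
      "higher_ref": 2.0
    },
    {
      "id": "orr",
      "name": "Objective response rate",
      "cluster": "therapeutic",
      "metric": "",
      "units": "% of patients",
      "kind": "continuous",
      "direction": "increasing",
      "minimum": 0.0,
      "maximum": 100.0,
      "lower_ref": 0.0,
      "higher_ref": 11.0
    },
    {
      "id": "os",
      "name": "Overall survival",
      "cluster": "therapeutic",
      "metric": "",
      "units": "months",
      "kind": "continuous",
      "direction": "increasing",
      "minimum": 0.0,
      "lower_ref": 0.0,
      "higher_ref": 6.2
    },
    {
      "id": "pfs",
      "name": "Progression free survival",
      "cluster": "therapeutic",
      "metric": "",
      "units": "months",
      "kind": "continuous",
      "direction": "increasing",
      "minimum": 0.0,
      "lower_ref": 0.0,
      "higher_ref": 1.9
    },
    {
      "id": "phase1",
      "name": "Phase 1",
      "cluster": "innovation",
      "metric": "",
      "units": "count",
      "kind": "continuous",
      "direction": "increasing",
      "minimum": 0.0,
      "lower_ref": 0.0,
      "higher_ref": 17.0
    },
    {
      "id": "phase2",
      "name": "Phase 2",
      "cluster": "innovation",
      "metric": "",
      "units": "count",
      "kind": "continuous",
      "direction": "increasing",
      "minimum": 0.0,
      "lower_ref": 0.0,
      "higher_ref": 55.0
    },
    {
      "id": "phase3",
      "name": "Phase 3",
      "cluster": "innovation",
      "metric": "",
      "units": "count",
      "kind": "continuous",
      "direction": "increasing",
      "minimum": 0.0,
      "lower_ref": 0.0,
      "higher_ref": 18.0
    },
    {
      "id": "posology",
      "name": "Posology",
      "cluster": "innovation",
      "metric": "",
      "units": "",
      "kind": "ordinal",
      "direction": "increasing",
      "lower_ref": "Many hours, every 2 weeks",
      "higher_ref": "Up to an hour, every 2 weeks",
      "levels": [
        "Many hours, every 2 weeks",
        "1 hour, every week",
        "Up to an hour, every 2 weeks"
      ]
    }
  ],
  "value_functions": [],
  "weights": {}
}
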