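{
  "schema_version": 1,
  "name": "om85-rrti-cua",
  "horizon": "6 months",
  "strategies": {
    "reference": "placebo",
    "intervention": "om85"
  },
  "parameters": [
    {
      "name": "p_repeat",
      "base_value": 0.2,
      "family": "beta",
      "sd": 0.05,
      "kind": "probability"
    },
    {
      "name": "p_mort",
      "base_value": 0.008,
      "family": "beta",
      "sd": 0.001,
      "kind": "probability"
    },
    {
      "name": "u_base",
      "base_value": 0.94,
      "family": "beta",
      "sd": 0.01,
      "kind": "utility"
    },
    {
      "name": "u_rti",
      "base_value": 0.87,
      "family": "beta",
      "sd": 0.2,
      "kind": "utility"
    },
    {
      "name": "c_rti",
      "base_value": 2022.0,
      "family": "gamma",
      "sd": 505.0,
      "kind": "cost"
    },
    {
      "name": "c_drug",
      "base_value": 74.0,
      "family": "gamma",
      "sd": 18.5,
      "kind": "cost"
    },
    {
      "name": "reduction",
      "base_value": 0.65,
      "family": "lognormal",
      "sd": 0.07,
      "kind": "effect"
    },
    {
      "name": "wtp",
      "base_value": 5180.0,
      "family": "fixed",
      "sd": 0.0,
      "kind": "wtp"
    }
  ],
  "analysis": {
    "wtp": 5180.0,
    "n_psa": 10000,
    "dsa_fraction": 0.25
  },
  "tree": {
    "kind": "decision",
    "strategies": {
      "om85": {
        "kind": "chance",
        "branches": [
          {
            "probability": "p_repeat * (1 - reduction)",
            "label": "repeat_rti",
            "child": {
              "kind": "chance",
              "branches": [
                {
                  "probability": "1 - p_mort",
                  "label": "survive",
                  "child": {
                    "kind": "terminal",
                    "cost": "(c_rti) + (c_drug)",
                    "utility": "u_rti"
                  }
                },
                {
                  "probability": "p_mort",
                  "label": "die",
                  "child": {
                    "kind": "terminal",
                    "cost": "(c_rti) + (c_drug)",
                    "utility": 0.0
                  }
                }
              ]
            }
          },
          {
            "probability": "1 - (p_repeat * (1 - reduction))",
            "label": "no_repeat",
            "child": {
              "kind": "terminal",
              "cost": "(0.0) + (c_drug)",
              "utility": "u_base"
            }
          }
        ]
      },
      "placebo": {
        "kind": "chance",
        "branches": [
          {
            "probability": "p_repeat",
            "label": "repeat_rti",
            "child": {
              "kind": "chance",
              "branches": [
                {
                  "probability": "1 - p_mort",
                  "label": "survive",
                  "child": {
                    "kind": "terminal",
                    "cost": "c_rti",
                    "utility": "u_rti"
                  }
                },
                {
                  "probability": "p_mort",
                  "label": "die",
                  "child": {
                    "kind": "terminal",
                    "cost": "c_rti",
                    "utility": 0.0
                  }
                }
              ]
            }
          },
          {
            "probability": "1 - (p_repeat)",
            "label": "no_repeat",
            "child": {
              "kind": "terminal",
              "cost": 0.0,
              "utility": "u_base"
            }
          }
        ]
      }
    }
  }
}
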