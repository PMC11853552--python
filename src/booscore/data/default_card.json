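{
  "name": "boo-risk-default",
  "rules": [
    {
      "variable": "age",
      "direction_note": "older age is higher risk",
      "bins": [
        {"lower": 0, "upper": 65, "lower_closed": true, "upper_closed": false, "points": 0},
        {"lower": 65, "upper": null, "lower_closed": true, "upper_closed": false, "points": 1}
      ]
    },
    {
      "variable": "ipss_vs",
      "direction_note": "higher voiding/storage ratio is higher risk",
      "bins": [
        {"lower": 0, "upper": 1.0, "lower_closed": true, "upper_closed": false, "points": 0},
        {"lower": 1.0, "upper": 2.0, "lower_closed": true, "upper_closed": false, "points": 1},
        {"lower": 2.0, "upper": null, "lower_closed": true, "upper_closed": false, "points": 2}
      ]
    },
    {
      "variable": "qmax",
      "direction_note": "lower maximum flow rate is higher risk",
      "bins": [
        {"lower": 0, "upper": 10, "lower_closed": true, "upper_closed": true, "points": 3},
        {"lower": 10, "upper": 13, "lower_closed": false, "upper_closed": false, "points": 2},
        {"lower": 13, "upper": 15, "lower_closed": true, "upper_closed": true, "points": 1},
        {"lower": 15, "upper": null, "lower_closed": false, "upper_closed": false, "points": 0}
      ]
    },
    {
      "variable": "voided_volume",
      "direction_note": "lower voided volume is higher risk",
      "bins": [
        {"lower": 0, "upper": 150, "lower_closed": true, "upper_closed": true, "points": 3},
        {"lower": 150, "upper": 201, "lower_closed": false, "upper_closed": false, "points": 2},
        {"lower": 201, "upper": 300, "lower_closed": true, "upper_closed": true, "points": 1},
        {"lower": 300, "upper": null, "lower_closed": false, "upper_closed": false, "points": 0}
      ]
    },
    {
      "variable": "tpv",
      "direction_note": "larger prostate volume is higher risk",
      "bins": [
        {"lower": 0, "upper": 30, "lower_closed": true, "upper_closed": false, "points": 0},
        {"lower": 30, "upper": 40, "lower_closed": true, "upper_closed": false, "points": 1},
        {"lower": 40, "upper": 50, "lower_closed": true, "upper_closed": false, "points": 2},
        {"lower": 50, "upper": null, "lower_closed": true, "upper_closed": false, "points": 3}
      ]
    },
    {
      "variable": "tzi",
      "direction_note": "larger transition-zone index is higher risk",
      "bins": [
        {"lower": 0, "upper": 0.30, "lower_closed": true, "upper_closed": true, "points": 0},
        {"lower": 0.30, "upper": 0.50, "lower_closed": false, "upper_closed": false, "points": 1},
        {"lower": 0.50, "upper": 1.0, "lower_closed": true, "upper_closed": true, "points": 2}
      ]
    },
    {
      "variable": "ipp",
      "direction_note": "larger intravesical protrusion is higher risk",
      "bins": [
        {"lower": 0, "upper": 0.5, "lower_closed": true, "upper_closed": false, "points": 0},
        {"lower": 0.5, "upper": 1.0, "lower_closed": true, "upper_closed": false, "points": 1},
        {"lower": 1.0, "upper": null, "lower_closed": true, "upper_closed": false, "points": 2}
      ]
    },
    {
      "variable": "puv_angle",
      "direction_note": "wider prostatic urethrovesical angle is higher risk",
      "bins": [
        {"lower": 0, "upper": 30, "lower_closed": true, "upper_closed": false, "points": 0},
        {"lower": 30, "upper": 40, "lower_closed": true, "upper_closed": false, "points": 1},
        {"lower": 40, "upper": 180, "lower_closed": true, "upper_closed": true, "points": 2}
      ]
    }
  ]
}
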