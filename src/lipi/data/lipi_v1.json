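{
  "name": "lipi_v1",
  "threshold": 1.5,
  "rules": [
    {
      "feature": "cyclophosphamide",
      "kind": "binary-exposure",
      "direction": "present",
      "cutoff": null,
      "points": 3
    },
    {
      "feature": "th17",
      "kind": "dichotomized-continuous",
      "direction": "greater",
      "cutoff": 8.0,
      "points": 2
    },
    {
      "feature": "b_cells",
      "kind": "dichotomized-continuous",
      "direction": "less",
      "cutoff": 60.5,
      "points": 1
    },
    {
      "feature": "tlr2_mfi",
      "kind": "dichotomized-continuous",
      "direction": "less",
      "cutoff": 1364.0,
      "points": 1
    }
  ]
}
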