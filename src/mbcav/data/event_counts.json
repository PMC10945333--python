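{
  "description": "Observed per-vessel vascular event tallies from the vascular-network-scale acquisitions (counts as printed; entries listed under 'derived' are reconstructed from printed totals by subtraction).",
  "total_vessels": 4742,
  "total_activations": 486,
  "pressure_groups": {
    "1.0": {
      "vessels": 1932,
      "activations": 38,
      "remained": 20,
      "extravasated": 13,
      "unclear": 5,
      "rbc_leakage": 17,
      "transient_reversals": 35,
      "derived": []
    },
    "2.0": {
      "vessels": 1402,
      "activations": 162,
      "remained": 29,
      "extravasated": 109,
      "unclear": 24,
      "rbc_leakage": 124,
      "transient_reversals": null,
      "derived": ["vessels", "remained", "extravasated", "unclear"]
    },
    "3.0": {
      "vessels": 1408,
      "activations": 286,
      "remained": 9,
      "extravasated": 226,
      "unclear": 51,
      "rbc_leakage": 255,
      "transient_reversals": 160,
      "derived": ["unclear"]
    }
  },
  "totals": {
    "extravasated": 348,
    "extravasated_with_leakage": 335,
    "remained": 58,
    "remained_with_leakage": 0
  },
  "timing_histogram_ms": [
    [0.0, 0.1, 0.038],
    [0.2, 0.3, 0.6],
    [0.4, 5.0, 0.362]
  ]
}
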