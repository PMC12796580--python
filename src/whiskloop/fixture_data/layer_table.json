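{
  "name": "layer_table",
  "provenance": "reported",
  "oracle": "published depth borders 65/320/540/775 um, half-open",
  "inputs": {
    "cases": [
      {"depth_um": 50, "layer": "outside"},
      {"depth_um": 65, "layer": "L2/3"},
      {"depth_um": 319, "layer": "L2/3"},
      {"depth_um": 320, "layer": "L4"},
      {"depth_um": 400, "layer": "L4"},
      {"depth_um": 539, "layer": "L4"},
      {"depth_um": 540, "layer": "L5"},
      {"depth_um": 774, "layer": "L5"},
      {"depth_um": 775, "layer": "L6"},
      {"depth_um": 800, "layer": "L6"},
      {"depth_um": 1200, "layer": "L6"}
    ]
  },
  "expected": {}
}
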