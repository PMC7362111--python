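{
  "comment": "Default secondary-structure regions of the (phi, psi) torus, degrees. Editable: these are documented literature-style rectangles, not an authoritative partition. Points on shared borders resolve to the lowest region id. The barrier partition groups compact helical states (A) against extended states (B); transitions between the groups cross the high-energy Ramachandran barrier.",
  "regions": [
    {"id": 0, "label": "PPII", "polygon": [[-110, 90], [-30, 90], [-30, 180], [-110, 180]]},
    {"id": 1, "label": "H2.5_1", "polygon": [[-180, 90], [-110, 90], [-110, 180], [-180, 180]]},
    {"id": 2, "label": "H3_10", "polygon": [[-120, -30], [-30, -30], [-30, 40], [-120, 40]]},
    {"id": 3, "label": "alphaR", "polygon": [[-120, -80], [-30, -80], [-30, -30], [-120, -30]]},
    {"id": 4, "label": "alphaL", "polygon": [[30, -20], [100, -20], [100, 80], [30, 80]]}
  ],
  "other_label": "other",
  "undefined_label": "undefined",
  "barrier_partition": {
    "A": ["H3_10", "alphaR", "alphaL"],
    "B": ["H2.5_1", "PPII"]
  }
}
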