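{
  "description": "Cross-tabulation of the published clustering solution (columns k1..k5) against the Goldberg knee-stiffness score (rows 0-4) and against the clinician-assigned chronic hemiparesis gait classification (rows G0..GIIIb). 115 subjects (96 hemiparetic patients, 19 healthy adults).",
  "clusters": ["k1", "k2", "k3", "k4", "k5"],
  "cluster_names": {
    "k1": "UKG (mild)",
    "k2": "BKG (moderate)",
    "k3": "FLG (severe)",
    "k4": "healthy",
    "k5": "non-SKG"
  },
  "goldberg": {
    "rows": ["0", "1", "2", "3", "4"],
    "counts": [
      [1, 0, 0, 17, 1],
      [9, 0, 0, 7, 14],
      [13, 5, 2, 4, 0],
      [11, 12, 5, 0, 0],
      [1, 11, 2, 0, 0]
    ]
  },
  "chgc": {
    "rows": ["G0", "GIa", "GIb", "GIIa", "GIIb", "GIIIa", "GIIIb"],
    "counts": [
      [1, 0, 0, 17, 1],
      [1, 0, 0, 4, 4],
      [0, 0, 0, 3, 9],
      [16, 9, 0, 1, 1],
      [15, 13, 4, 2, 0],
      [1, 2, 1, 0, 0],
      [1, 4, 4, 1, 0]
    ]
  }
}
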