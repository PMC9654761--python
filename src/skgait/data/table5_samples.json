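{
  "description": "Published comparison of the present SKG study sample against target samples from earlier SKG studies. Each row carries the present-sample central value and one central value per target study; similarity scores (S) are 100*min/max rounded half-up, and each block's generalizability score (G) is the rounded mean of its S scores. Central values are means for mean+/-SD entries and medians for ordinal entries. 'printed_s' / 'printed_g' record the published scores for cross-checking.",
  "blocks": {
    "demographic": {
      "rows": [
        {"variable": "sex_pct_women", "present": 39, "targets": [45, 30], "printed_s": [87, 77]},
        {"variable": "age_years", "present": 55, "targets": [55, 57], "printed_s": [100, 96]},
        {"variable": "weight_kg", "present": 80, "targets": [74, 67, 73], "printed_s": [93, 84, 91]}
      ],
      "printed_g": 90
    },
    "clinical": {
      "rows": [
        {"variable": "hemiparetic_side_pct_left", "present": 45, "targets": [31, 48], "printed_s": [69, 94]},
        {"variable": "time_since_stroke_months", "present": 54, "targets": [83, 53], "printed_s": [65, 98]},
        {"variable": "mAS_4ceps", "present": 1, "targets": [2, 1, 2.5], "printed_s": [50, 100, 40]},
        {"variable": "MRC_hip", "present": 3, "targets": [3], "printed_s": [100]},
        {"variable": "MRC_ankle", "present": 1, "targets": [3], "printed_s": [33]}
      ],
      "printed_g": 72
    },
    "gait": {
      "rows": [
        {"variable": "velocity_m_s", "present": 0.56, "targets": [0.58, 0.57, 0.54], "printed_s": [97, 98, 96]},
        {"variable": "K5_deg", "present": 25, "targets": [25, 30], "printed_s": [100, 83]}
      ],
      "printed_g": 95
    }
  }
}
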