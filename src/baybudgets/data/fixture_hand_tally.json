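{
  "comment": "Hand-counted expectations for the toy fixture CSVs. Counted manually from fixture_sightings.csv / fixture_acoustic.csv / fixture_scans.csv.",
  "occurrence_counts": {
    "D1": {"Makako": 2, "Kealakekua": 1, "Honaunau": 0, "Kauhako": 0},
    "D2": {"Makako": 1, "Kealakekua": 0, "Honaunau": 0, "Kauhako": 0},
    "D3": {"Makako": 0, "Kealakekua": 1, "Honaunau": 0, "Kauhako": 1},
    "D4": {"Makako": 3, "Kealakekua": 0, "Honaunau": 0, "Kauhako": 0},
    "D5": {"Makako": 0, "Kealakekua": 0, "Honaunau": 1, "Kauhako": 0}
  },
  "allocation_probs": {
    "D1": {"Makako": 0.6666666666666666, "Kealakekua": 0.3333333333333333, "Honaunau": 0.0, "Kauhako": 0.0},
    "D2": {"Makako": 1.0, "Kealakekua": 0.0, "Honaunau": 0.0, "Kauhako": 0.0},
    "D3": {"Makako": 0.0, "Kealakekua": 0.5, "Honaunau": 0.0, "Kauhako": 0.5},
    "D4": {"Makako": 1.0, "Kealakekua": 0.0, "Honaunau": 0.0, "Kauhako": 0.0},
    "D5": {"Makako": 0.0, "Kealakekua": 0.0, "Honaunau": 1.0, "Kauhako": 0.0}
  },
  "bay_use_pct": {"Makako": 60, "Kealakekua": 40, "Honaunau": 20, "Kauhako": 20},
  "presence_probability": {
    "Makako": 0.9166666666666666,
    "Kealakekua": 0.6,
    "Honaunau": 0.3333333333333333,
    "Kauhako": 0.5
  },
  "missing_days": {"Makako": 0, "Kealakekua": 2, "Honaunau": 0, "Kauhako": 0},
  "point_budgets": {
    "Makako": [0.6666666666666666, 0.16666666666666666, 0.16666666666666666],
    "Kealakekua": [0.75, 0.25, 0.0],
    "Honaunau": [0.6666666666666666, 0.3333333333333333, 0.0],
    "Kauhako": [0.6666666666666666, 0.0, 0.3333333333333333],
    "OUTSIDE": [0.2, 0.2, 0.6]
  },
  "time_inside": {
    "Makako": [0.08333333333333333],
    "Kealakekua": [0.05555555555555555],
    "Honaunau": [0.041666666666666664],
    "Kauhako": [0.041666666666666664]
  },
  "exposure": {
    "overall_proportion": 0.6666666666666666,
    "approached_scans": 14,
    "total_scans": 21,
    "control_fraction_boat": 0.42857142857142855,
    "control_fraction_land": 0.14285714285714285,
    "f01_runs": [["UNAPPROACHED", 2], ["APPROACHED", 3], ["UNAPPROACHED", 1]],
    "f03_runs": [["APPROACHED", 1], ["UNAPPROACHED", 2], ["APPROACHED", 2]]
  }
}
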