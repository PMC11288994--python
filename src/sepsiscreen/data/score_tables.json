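{
  "schema_version": "1",
  "comment": "Prehospital-adapted screening score tables. Interval components list ascending break values b_1..b_k and k+1 point entries; a quantized measurement v maps to points[i] where i is the number of breaks <= v. Quantization: one decimal for temperature, integers elsewhere, half-up. SIRS omits the leukocyte and paCO2 criteria and MEWS omits urine output (not available prehospital).",
  "tools": {
    "qsofa": {
      "name": "qSOFA",
      "threshold": 2,
      "max_score": 3,
      "components": {
        "rr": {"kind": "interval", "breaks": [22], "points": [0, 1]},
        "sbp": {"kind": "interval", "breaks": [101], "points": [1, 0]},
        "gcs": {"kind": "interval", "breaks": [15], "points": [1, 0]}
      }
    },
    "sirs": {
      "name": "SIRS (prehospital)",
      "threshold": 2,
      "max_score": 3,
      "components": {
        "temp": {"kind": "interval", "breaks": [36.0, 38.1], "points": [1, 0, 1]},
        "hr": {"kind": "interval", "breaks": [91], "points": [0, 1]},
        "rr": {"kind": "interval", "breaks": [21], "points": [0, 1]}
      }
    },
    "mews": {
      "name": "MEWS (prehospital)",
      "threshold": 4,
      "max_score": 14,
      "components": {
        "sbp": {"kind": "interval", "breaks": [71, 81, 101, 200], "points": [3, 2, 1, 0, 2]},
        "hr": {"kind": "interval", "breaks": [41, 51, 101, 111, 130], "points": [2, 1, 0, 1, 2, 3]},
        "rr": {"kind": "interval", "breaks": [9, 15, 21, 30], "points": [2, 0, 1, 2, 3]},
        "temp": {"kind": "interval", "breaks": [35.0, 38.5], "points": [2, 0, 2]},
        "consciousness": {"kind": "category", "points": {"A": 0, "C": 1, "V": 1, "P": 2, "U": 3}}
      }
    },
    "news2": {
      "name": "NEWS2",
      "threshold": 5,
      "max_score": 20,
      "components": {
        "rr": {"kind": "interval", "breaks": [9, 12, 21, 25], "points": [3, 1, 0, 2, 3]},
        "spo2": {"kind": "interval", "breaks": [92, 94, 96], "points": [3, 2, 1, 0]},
        "on_oxygen": {"kind": "category", "points": {"false": 0, "true": 2}},
        "sbp": {"kind": "interval", "breaks": [91, 101, 111, 220], "points": [3, 2, 1, 0, 3]},
        "hr": {"kind": "interval", "breaks": [41, 51, 91, 111, 131], "points": [3, 1, 0, 1, 2, 3]},
        "consciousness": {"kind": "category", "points": {"A": 0, "C": 3, "V": 3, "P": 3, "U": 3}},
        "temp": {"kind": "interval", "breaks": [35.1, 36.1, 38.1, 39.1], "points": [3, 1, 0, 1, 2]}
      }
    }
  }
}
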