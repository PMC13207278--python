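{
 "schema": "fuzzymcda/decision-matrix@1",
 "alternatives": [
  {"code": "A1", "name": "PLA/Hydroxyapatite (PLA/HA)"},
  {"code": "A2", "name": "PCL/Hydroxyapatite (PCL/HA)"},
  {"code": "A3", "name": "PLGA/Bioactive Glass (PLGA/BG)"},
  {"code": "A4", "name": "PLA/Carbon Nanotubes (PLA/CNT)"},
  {"code": "A5", "name": "PLA/Magnesium (PLA/Mg)"}
 ],
 "criteria": [
  {"id": "C1", "name": "Compressive Strength", "units": "MPa", "direction": "benefit", "weight": [0.20, 0.25, 0.30]},
  {"id": "C2", "name": "Elastic Modulus", "units": "GPa", "direction": "benefit", "weight": [0.15, 0.20, 0.25]},
  {"id": "C3", "name": "Porosity", "units": "%", "direction": "benefit", "weight": [0.10, 0.15, 0.20]},
  {"id": "C4", "name": "Degradation Rate", "units": "weeks", "direction": "target_range", "target_window": [12, 26], "decay_anchor": 200, "weight": [0.10, 0.15, 0.20]},
  {"id": "C5", "name": "Cell Viability", "units": "%", "direction": "benefit", "weight": [0.15, 0.20, 0.25]},
  {"id": "C6", "name": "Manufacturing Cost Index", "units": "1-9 scale", "direction": "cost", "weight": [0.05, 0.05, 0.10]}
 ],
 "matrix": [
  [[20, 45, 65], [1.5, 3.5, 6.0], [40, 60, 70], [24, 48, 100], [85, 92, 99], [1, 3, 5]],
  [[3.5, 7.0, 11], [0.1, 0.2, 0.4], [60, 75, 90], [50, 100, 200], [90, 95, 99], [1, 3, 5]],
  [[2.0, 5.0, 15], [0.5, 1.0, 3.0], [80, 90, 95], [4, 8, 12], [90, 96, 99], [3, 5, 7]],
  [[35, 47, 60], [1.2, 1.7, 2.5], [20, 40, 50], [24, 48, 72], [75, 85, 90], [5, 7, 9]],
  [[15, 30, 52], [0.8, 1.5, 2.2], [30, 55, 70], [12, 16, 24], [85, 90, 95], [3, 5, 7]]
 ],
 "weights": {
  "schema": "fuzzymcda/weights@1",
  "criteria": [
   {"id": "C1", "priority": "Very High", "local_weight": [0.20, 0.25, 0.30], "global_weight": 25.2},
   {"id": "C2", "priority": "High", "local_weight": [0.15, 0.20, 0.25], "global_weight": 18.4},
   {"id": "C3", "priority": "Medium", "local_weight": [0.10, 0.15, 0.20], "global_weight": 12.1},
   {"id": "C4", "priority": "Medium", "local_weight": [0.10, 0.15, 0.20], "global_weight": 12.1},
   {"id": "C5", "priority": "High", "local_weight": [0.15, 0.20, 0.25], "global_weight": 21.5},
   {"id": "C6", "priority": "Low", "local_weight": [0.05, 0.05, 0.10], "global_weight": 10.7}
  ]
 },
 "notes": {
  "c6_assumption": "The published master matrix reports criteria C1-C5 only. The manufacturing-cost column (C6) uses the package's documented default linguistic ratings (A1 L, A2 L, A3 M, A4 H, A5 M) mapped through the five-term scale; any result depending on C6 holds under this assumption and the column can be overridden.",
  "c4_handling": "Degradation rate is scored against a 12-26 week target window (desirability 1 inside the window, rising linearly from 0 weeks below it, decaying linearly to 0 at the decay anchor above it)."
 }
}
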