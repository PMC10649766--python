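{
 "term_labels": [
  "A", "B", "C", "D", "E", "F", "G",
  "AxB", "AxC", "AxD", "AxE", "AxF", "AxG",
  "BxC", "BxD", "BxE", "BxF", "BxG",
  "CxD", "CxE", "CxF", "CxG",
  "DxE", "DxF", "DxG",
  "ExF", "ExG",
  "FxG",
  "Constant"
 ],
 "coefficients": [
  0.165404, -0.626781, -0.43888, -0.181944, 0.231918, 0.34817, -0.37727,
  -0.578918, 0.131548, 0.255888, -0.035711, 0.255385, -0.358334,
  1.366192, 0.127896, -1.453575, -0.291472, 0.19813,
  0.372922, 0.437779, -0.661009, 0.734438,
  0.068061, -0.678175, 0.10932,
  0.417461, -0.803023,
  -0.590657,
  -0.419399
 ],
 "bounds": {
  "age": [24.0, 90.0],
  "kvp": [70.0, 140.0],
  "bsa": [1.27, 2.7],
  "hr": [45.0, 139.0],
  "co": [4.18, 11.11],
  "cm": [17.0, 75.0],
  "dtt": [2.0, 5.13],
  "cta_la_over_400": [0.61, 2.17]
 },
 "target_cta": 400.0,
 "metadata": {
  "description": "Reference 29-term coefficient set for the head-and-neck CTA left-artery model, with the derivation cohort's factor bounds (n=450). Factors: A age (yr), B tube voltage (kVp), C BSA (m^2), D heart rate (/min), E cardiac output (L/min), F contrast volume (c.c.), G trigger delay (s).",
  "n": 450
 }
}
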