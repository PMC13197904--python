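{
 "sex": "male",
 "outcome": "appendicular_lst",
 "scale": "log",
 "intercept": 0.75,
 "coefficients": {
  "appendicular_mass": 0.63,
  "height": 0.48,
  "I_Black": 0.05,
  "I_Asian": -0.004
 },
 "transforms": {
  "appendicular_mass": "log",
  "height": "log",
  "I_Black": "identity",
  "I_Asian": "identity"
 },
 "units": {"height": "m", "appendicular_mass": "kg"},
 "provenance": "dietfits-table4",
 "test_r2": null
}
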