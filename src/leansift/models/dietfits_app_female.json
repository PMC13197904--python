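{
 "sex": "female",
 "outcome": "appendicular_lst",
 "scale": "log",
 "intercept": 0.33,
 "coefficients": {
  "appendicular_mass": 0.60,
  "height": 1.03,
  "I_Black": 0.02,
  "I_OtherRace": 0.02
 },
 "transforms": {
  "appendicular_mass": "log",
  "height": "log",
  "I_Black": "identity",
  "I_OtherRace": "identity"
 },
 "units": {"height": "m", "appendicular_mass": "kg"},
 "provenance": "dietfits-table4",
 "test_r2": null
}
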