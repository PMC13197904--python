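{
 "sex": "male",
 "outcome": "total_lst",
 "scale": "linear",
 "intercept": -14.729,
 "coefficients": {
  "age": -0.071,
  "height": 0.210,
  "weight": 0.468,
  "I_Mexican": -0.441,
  "I_Hispanic": 0.320,
  "I_Black": 1.821,
  "I_OtherRace": -0.784
 },
 "transforms": {
  "age": "identity",
  "height": "identity",
  "weight": "identity",
  "I_Mexican": "identity",
  "I_Hispanic": "identity",
  "I_Black": "identity",
  "I_OtherRace": "identity"
 },
 "units": {"height": "cm", "weight": "kg", "age": "y"},
 "provenance": "nhanes",
 "test_r2": 0.88
}
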