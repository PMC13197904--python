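{
 "sex": "female",
 "outcome": "total_lst",
 "scale": "linear",
 "intercept": -14.292,
 "coefficients": {
  "age": -0.046,
  "height": 0.201,
  "weight": 0.347,
  "I_Mexican": -0.448,
  "I_Hispanic": -0.047,
  "I_Black": 1.128,
  "I_OtherRace": -0.384
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
 "test_r2": 0.85
}
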