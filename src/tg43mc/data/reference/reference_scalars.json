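{
 "this-work-NNDC": {
  "Sk_per_A_U_per_Bq": 1.0139e-07,
  "Lambda_cGy_per_h_per_U": 1.11,
  "gL_fit_coefficients": [
   0.993,
   0.007834,
   -0.0007279,
   -0.0001243,
   8.184e-06,
   -1.528e-07
  ]
 },
 "this-work-DC": {
  "Sk_per_A_U_per_Bq": 9.853e-08,
  "Lambda_cGy_per_h_per_U": 1.106,
  "gL_fit_coefficients": [
   0.9981,
   0.00768,
   -0.0005617,
   -0.0001419,
   8.622e-06,
   -1.49e-07
  ]
 },
 "consensus": {
  "Sk_per_A_U_per_Bq": 9.79e-08,
  "Lambda_cGy_per_h_per_U": 1.117
 }
}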