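# Ir-192 photon emission spectrum, NNDC evaluation (gammas + K/L x rays > 10 keV)
# intensities normalised to a 2.363 photons/decay total; see data/manifest.json
energy_MeV,photons_per_decay
0.010510,2.533095e-03
0.011070,2.229124e-02
0.012420,5.066191e-04
0.012940,5.572810e-03
0.061486,1.205753e-02
0.063000,2.077138e-02
0.065122,2.664816e-02
0.066831,4.589969e-02
0.071079,2.431772e-03
0.071413,4.681160e-03
0.073363,1.651578e-03
0.075368,5.370162e-03
0.075749,1.034516e-02
0.077850,3.667922e-03
0.136343,2.016344e-03
0.176980,4.356924e-05
0.201311,4.772352e-03
0.205794,3.384215e-02
0.283267,2.695213e-03
0.295956,2.909007e-01
0.308455,3.009317e-01
0.316506,8.395691e-01
0.329170,1.763034e-04
0.374485,7.356109e-03
0.416469,6.788695e-03
0.420520,6.991343e-04
0.468069,4.847331e-01
0.484575,3.231216e-02
0.489060,4.437983e-03
0.588581,4.581863e-02
0.593490,4.265733e-04
0.599410,3.951629e-05
0.604411,8.324764e-02
0.612462,5.410692e-02
0.703850,5.370162e-05
0.765800,1.317210e-05
0.884537,2.948523e-03
0.920930,8.105905e-05
1.061480,5.370162e-04
1.089900,1.215886e-05
1.378200,1.215886e-05
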