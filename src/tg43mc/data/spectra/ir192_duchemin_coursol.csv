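# Ir-192 photon emission spectrum, Duchemin & Coursol (1995) lineage
# kept verbatim per source, including the 9.44 keV L-alpha group below the 10 keV cutoff
energy_MeV,photons_per_decay
0.009440,4.100000e-02
0.011070,2.600000e-02
0.012940,6.000000e-03
0.061486,1.200000e-02
0.063000,2.050000e-02
0.065122,2.700000e-02
0.066831,4.600000e-02
0.071250,7.000000e-03
0.073360,1.600000e-03
0.075550,1.550000e-02
0.077850,3.600000e-03
0.136343,1.830000e-03
0.201311,4.730000e-03
0.205794,3.300000e-02
0.283267,2.690000e-03
0.295956,2.872000e-01
0.308455,2.968000e-01
0.316506,8.275000e-01
0.329170,1.720000e-04
0.374485,7.270000e-03
0.416469,6.700000e-03
0.420520,6.900000e-04
0.468069,4.781000e-01
0.484575,3.187000e-02
0.489060,4.270000e-03
0.588581,4.520000e-02
0.604411,8.230000e-02
0.612462,5.310000e-02
0.884537,2.880000e-03
1.061480,5.310000e-04
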