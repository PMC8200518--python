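# per-process mass attenuation for air, cm^2/g
energy_MeV,mu_photoelectric,mu_incoherent,mu_coherent,mu_total,mu_en
1.000000e-02,4.741020e+00,1.641370e-01,2.148433e-01,5.120000e+00,4.742000e+00
1.500000e-02,1.317501e+00,1.728018e-01,1.236974e-01,1.614000e+00,1.334000e+00
2.000000e-02,5.217723e-01,1.751598e-01,8.096790e-02,7.779000e-01,5.389000e-01
3.000000e-02,1.370441e-01,1.740432e-01,4.271267e-02,3.538000e-01,1.537000e-01
4.000000e-02,5.156597e-02,1.705507e-01,2.638329e-02,2.485000e-01,6.833000e-02
5.000000e-02,2.361305e-02,1.664827e-01,1.790423e-02,2.080000e-01,4.098000e-02
6.000000e-02,1.220291e-02,1.623563e-01,1.294081e-02,1.875000e-01,3.041000e-02
8.000000e-02,4.014184e-03,1.545276e-01,7.658199e-03,1.662000e-01,2.407000e-02
1.000000e-01,1.556000e-03,1.474910e-01,5.053024e-03,1.541000e-01,2.325000e-02
1.500000e-01,1.619220e-04,1.331016e-01,2.336450e-03,1.356000e-01,2.496000e-02
2.000000e-01,1.000000e-08,1.220658e-01,1.338788e-03,1.234046e-01,2.672000e-02
3.000000e-01,1.000000e-08,1.062048e-01,6.050188e-04,1.068098e-01,2.872000e-02
4.000000e-01,1.000000e-08,9.517582e-02,3.427954e-04,9.551863e-02,2.949000e-02
5.000000e-01,1.000000e-08,8.691525e-02,2.202340e-04,8.713550e-02,2.966000e-02
6.000000e-01,1.000000e-08,8.040631e-02,1.532931e-04,8.055961e-02,2.953000e-02
8.000000e-01,2.408998e-05,7.062946e-02,8.644610e-05,7.074000e-02,2.882000e-02
1.000000e+00,3.367274e-05,6.349093e-02,5.539764e-05,6.358000e-02,2.789000e-02
1.250000e+00,7.308862e-05,5.676142e-02,3.548662e-05,5.687000e-02,2.666000e-02
1.500000e+00,1.471306e-04,5.157821e-02,2.465651e-05,5.175000e-02,2.547000e-02
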