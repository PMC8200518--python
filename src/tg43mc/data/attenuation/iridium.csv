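# per-process mass attenuation for iridium, cm^2/g
energy_MeV,mu_photoelectric,mu_incoherent,mu_coherent,mu_total
1.000000e-02,4.230222e+02,1.001478e-01,4.298351e+00,4.274207e+02
1.120615e-02,3.175146e+02,1.051192e-01,3.858746e+00,3.214785e+02
1.255779e-02,2.376878e+02,1.097388e-01,3.439563e+00,2.412371e+02
1.407245e-02,1.774834e+02,1.139500e-01,3.044844e+00,1.806422e+02
1.500000e-02,1.505231e+02,1.161142e-01,2.835543e+00,1.534748e+02
1.576981e-02,1.322154e+02,1.177071e-01,2.677818e+00,1.350109e+02
1.767189e-02,9.827549e+01,1.209783e-01,2.340651e+00,1.007371e+02
1.980340e-02,7.289748e+01,1.237459e-01,2.034370e+00,7.505560e+01
2.000000e-02,7.102617e+01,1.239621e-01,2.009262e+00,7.315939e+01
2.219199e-02,5.396964e+01,1.260059e-01,1.758942e+00,5.585459e+01
2.486869e-02,3.988611e+01,1.277639e-01,1.513454e+00,4.152733e+01
2.786824e-02,2.942826e+01,1.290346e-01,1.296342e+00,3.085364e+01
3.000000e-02,2.414798e+01,1.296062e-01,1.170018e+00,2.544761e+01
3.122958e-02,2.167475e+01,1.298373e-01,1.105620e+00,2.291021e+01
3.499636e-02,1.593853e+01,1.301946e-01,9.390720e-01,1.700780e+01
3.921746e-02,1.169741e+01,1.301304e-01,7.944069e-01,1.262195e+01
4.000000e-02,1.108417e+01,1.300782e-01,7.713680e-01,1.198562e+01
4.394769e-02,8.571888e+00,1.296693e-01,6.693683e-01,9.370925e+00
4.924846e-02,6.271814e+00,1.288355e-01,5.618031e-01,6.962453e+00
5.000000e-02,6.015906e+00,1.286979e-01,5.487048e-01,6.693309e+00
5.518859e-02,4.583771e+00,1.276531e-01,4.697006e-01,5.181125e+00
6.000000e-02,3.639851e+00,1.265771e-01,4.108556e-01,4.177283e+00
6.184519e-02,3.347694e+00,1.261458e-01,3.912081e-01,3.865047e+00
6.930468e-02,2.442841e+00,1.243371e-01,3.246326e-01,2.891810e+00
7.611000e-02,1.883927e+00,1.226403e-01,2.777148e-01,2.284282e+00
7.611200e-02,9.235203e+00,1.226398e-01,2.777026e-01,9.635546e+00
7.766389e-02,8.768002e+00,1.222508e-01,2.684349e-01,9.158687e+00
8.000000e-02,8.123904e+00,1.216653e-01,2.553362e-01,8.500905e+00
8.703136e-02,6.536078e+00,1.199109e-01,2.212218e-01,6.877210e+00
9.752869e-02,4.862426e+00,1.173417e-01,1.817391e-01,5.161506e+00
1.000000e-01,4.554857e+00,1.167489e-01,1.739854e-01,4.845591e+00
1.092922e-01,3.607370e+00,1.145682e-01,1.488652e-01,3.870803e+00
1.224745e-01,2.667647e+00,1.116155e-01,1.216059e-01,2.900869e+00
1.372468e-01,1.967721e+00,1.085093e-01,9.908786e-02,2.175318e+00
1.500000e-01,1.549833e+00,1.059955e-01,8.431813e-02,1.740147e+00
1.538009e-01,1.449004e+00,1.052752e-01,8.055138e-02,1.634830e+00
1.723517e-01,1.067485e+00,1.019387e-01,6.534144e-02,1.234765e+00
1.931399e-01,7.863822e-01,9.852431e-02,5.289801e-02,9.378045e-01
2.000000e-01,7.161162e-01,9.746594e-02,4.956288e-02,8.631450e-01
2.164356e-01,5.798285e-01,9.507785e-02,4.274573e-02,7.176521e-01
2.425411e-01,4.284170e-01,9.157812e-02,3.448369e-02,5.544788e-01
2.717953e-01,3.172215e-01,8.806553e-02,2.777569e-02,4.330627e-01
3.000000e-01,2.450634e-01,8.502341e-02,2.299932e-02,3.530861e-01
3.045780e-01,2.356123e-01,8.455776e-02,2.234119e-02,3.425112e-01
3.413149e-01,1.757658e-01,8.107036e-02,1.794718e-02,2.747834e-01
3.824827e-01,1.317252e-01,7.761671e-02,1.440091e-02,2.237428e-01
4.000000e-01,1.177619e-01,7.627039e-02,1.320291e-02,2.072353e-01
4.286161e-01,9.923385e-02,7.420811e-02,1.154357e-02,1.849855e-01
4.803138e-01,7.519673e-02,7.085383e-02,9.244779e-03,1.552953e-01
5.000000e-01,6.829230e-02,6.968507e-02,8.546582e-03,1.465240e-01
5.382471e-01,5.736192e-02,6.756134e-02,7.397838e-03,1.323211e-01
6.000000e-01,4.457066e-02,6.448412e-02,5.977284e-03,1.150321e-01
6.031680e-01,4.403538e-02,6.433655e-02,5.915719e-03,1.142877e-01
6.759194e-01,3.405598e-02,6.118411e-02,4.727629e-03,9.996772e-02
7.574458e-01,2.650970e-02,5.810769e-02,3.776132e-03,8.839352e-02
8.000000e-01,2.356325e-02,5.665894e-02,3.389451e-03,8.361164e-02
8.488055e-01,2.079641e-02,5.511025e-02,3.014743e-03,7.892139e-02
9.511845e-01,1.642061e-02,5.219428e-02,2.405917e-03,7.102081e-02
1.000000e+00,1.484801e-02,5.093912e-02,2.178596e-03,6.796573e-02
1.065912e+00,1.318974e-02,4.936200e-02,1.919388e-03,6.447113e-02
1.194478e+00,1.092196e-02,4.661544e-02,1.530800e-03,5.906820e-02
1.250000e+00,1.019617e-02,4.554398e-02,1.398589e-03,5.713874e-02
1.338550e+00,9.382921e-03,4.395652e-02,1.220580e-03,5.456003e-02
1.500000e+00,8.714728e-03,4.138711e-02,9.730220e-04,5.107486e-02
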