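# per-process mass attenuation for steel304, cm^2/g
energy_MeV,mu_photoelectric,mu_incoherent,mu_coherent,mu_total
1.000000e-02,1.646206e+02,1.360481e-01,1.150594e+00,1.659073e+02
1.120615e-02,1.212007e+02,1.406283e-01,1.010613e+00,1.223520e+02
1.255779e-02,8.892642e+01,1.446647e-01,8.823225e-01,8.995341e+01
1.407245e-02,6.503818e+01,1.481404e-01,7.660332e-01,6.595236e+01
1.500000e-02,5.450645e+01,1.498420e-01,7.060806e-01,5.536237e+01
1.576981e-02,4.742696e+01,1.510534e-01,6.616560e-01,4.823967e+01
1.767189e-02,3.449124e+01,1.534126e-01,5.687787e-01,3.521343e+01
1.980340e-02,2.502225e+01,1.552355e-01,4.867551e-01,2.566424e+01
2.000000e-02,2.433260e+01,1.553691e-01,4.801260e-01,2.496809e+01
2.219199e-02,1.808925e+01,1.565451e-01,4.147916e-01,1.866059e+01
2.486869e-02,1.301974e+01,1.573665e-01,3.520196e-01,1.352913e+01
2.786824e-02,9.342122e+00,1.577257e-01,2.975511e-01,9.797399e+00
3.000000e-02,7.528294e+00,1.577240e-01,2.663120e-01,7.952330e+00
3.122958e-02,6.690208e+00,1.576484e-01,2.505178e-01,7.098374e+00
3.499636e-02,4.776302e+00,1.571589e-01,2.100954e-01,5.143556e+00
3.921746e-02,3.401175e+00,1.562803e-01,1.755166e-01,3.732972e+00
4.000000e-02,3.206049e+00,1.560899e-01,1.700591e-01,3.532198e+00
4.394769e-02,2.416893e+00,1.550345e-01,1.460757e-01,2.718004e+00
4.924846e-02,1.713331e+00,1.534424e-01,1.211289e-01,1.987902e+00
5.000000e-02,1.636489e+00,1.532056e-01,1.181178e-01,1.907812e+00
5.518859e-02,1.212242e+00,1.515241e-01,1.000911e-01,1.463858e+00
6.000000e-02,9.390222e-01,1.499200e-01,8.682782e-02,1.175770e+00
6.184519e-02,8.557764e-01,1.492995e-01,8.243333e-02,1.087509e+00
6.930468e-02,6.029895e-01,1.467889e-01,6.768000e-02,8.174584e-01
7.611000e-02,4.515575e-01,1.445240e-01,5.742109e-02,6.535026e-01
7.611200e-02,4.515208e-01,1.445233e-01,5.741842e-02,6.534625e-01
7.766389e-02,4.241837e-01,1.440128e-01,5.540655e-02,6.236030e-01
8.000000e-02,3.869839e-01,1.432494e-01,5.257162e-02,5.828049e-01
8.703136e-02,2.979050e-01,1.409926e-01,4.523729e-02,4.841349e-01
9.752869e-02,2.088452e-01,1.377505e-01,3.684287e-02,3.834386e-01
1.000000e-01,1.931288e-01,1.370107e-01,3.520698e-02,3.653465e-01
1.092922e-01,1.462001e-01,1.343101e-01,2.993731e-02,3.104475e-01
1.224745e-01,1.022194e-01,1.306956e-01,2.427449e-02,2.571895e-01
1.372468e-01,7.142257e-02,1.269326e-01,1.964428e-02,2.179995e-01
1.500000e-01,5.399105e-02,1.239095e-01,1.663304e-02,1.945336e-01
1.538009e-01,4.989747e-02,1.230517e-01,1.586859e-02,1.888177e-01
1.723517e-01,3.481866e-02,1.190890e-01,1.279737e-02,1.667051e-01
1.931399e-01,2.431912e-02,1.150329e-01,1.030494e-02,1.496570e-01
2.000000e-01,2.180159e-02,1.137788e-01,9.640293e-03,1.452207e-01
2.164356e-01,1.704025e-02,1.109276e-01,8.286528e-03,1.362543e-01
2.425411e-01,1.196202e-02,1.067959e-01,6.655172e-03,1.254131e-01
2.717953e-01,8.416356e-03,1.026592e-01,5.339009e-03,1.164145e-01
3.000000e-01,6.219618e-03,9.908346e-02,4.406936e-03,1.097100e-01
3.045780e-01,5.938589e-03,9.853665e-02,4.278866e-03,1.087541e-01
3.413149e-01,4.194004e-03,9.444537e-02,3.426197e-03,1.020656e-01
3.824827e-01,2.978797e-03,9.039993e-02,2.741300e-03,9.612002e-02
4.000000e-01,2.612583e-03,8.882439e-02,2.510647e-03,9.394763e-02
4.286161e-01,2.140769e-03,8.641247e-02,2.191812e-03,9.074505e-02
4.803138e-01,1.556424e-03,8.249287e-02,1.751420e-03,8.580072e-02
5.000000e-01,1.396703e-03,8.112802e-02,1.617984e-03,8.414271e-02
5.382471e-01,1.150951e-03,7.864898e-02,1.398788e-03,8.119872e-02
6.000000e-01,8.786300e-04,7.505899e-02,1.128358e-03,7.706598e-02
6.031680e-01,8.677129e-04,7.488690e-02,1.116654e-03,7.687126e-02
6.759194e-01,6.633195e-04,7.121137e-02,8.910822e-04,7.276577e-02
7.574458e-01,5.152900e-04,6.762610e-02,7.108422e-04,6.885224e-02
8.000000e-01,4.615966e-04,6.593820e-02,6.377061e-04,6.703750e-02
8.488055e-01,4.092196e-04,6.413412e-02,5.668995e-04,6.511024e-02
9.511845e-01,3.321672e-04,6.073798e-02,4.519959e-04,6.152215e-02
1.000000e+00,3.156771e-04,5.927636e-02,4.091413e-04,6.000118e-02
1.065912e+00,3.043311e-04,5.744000e-02,3.603085e-04,5.810464e-02
1.194478e+00,2.931305e-04,5.424236e-02,2.871705e-04,5.482266e-02
1.250000e+00,2.929626e-04,5.299505e-02,2.623062e-04,5.355032e-02
1.338550e+00,3.284544e-04,5.114717e-02,2.288453e-04,5.170447e-02
1.500000e+00,5.353127e-04,4.815648e-02,1.823438e-04,4.887413e-02
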