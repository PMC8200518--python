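# per-process mass attenuation for steel316l, cm^2/g
energy_MeV,mu_photoelectric,mu_incoherent,mu_coherent,mu_total
1.000000e-02,1.680309e+02,1.356798e-01,1.180261e+00,1.693469e+02
1.120615e-02,1.238387e+02,1.402746e-01,1.037162e+00,1.250161e+02
1.255779e-02,9.095458e+01,1.443274e-01,9.059058e-01,9.200482e+01
1.407245e-02,6.658860e+01,1.478203e-01,7.868356e-01,6.752325e+01
1.500000e-02,5.583733e+01,1.495316e-01,7.254146e-01,5.671228e+01
1.576981e-02,4.860643e+01,1.507507e-01,6.798867e-01,4.943707e+01
1.767189e-02,3.538427e+01,1.531271e-01,5.846610e-01,3.612206e+01
1.980340e-02,2.569543e+01,1.549665e-01,5.005168e-01,2.635091e+01
2.000000e-02,2.498934e+01,1.551015e-01,4.937144e-01,2.563816e+01
2.219199e-02,1.930762e+01,1.562916e-01,4.266568e-01,1.989057e+01
2.486869e-02,1.393345e+01,1.571276e-01,3.622026e-01,1.445278e+01
2.786824e-02,1.002451e+01,1.575003e-01,3.062524e-01,1.048826e+01
3.000000e-02,8.091780e+00,1.575066e-01,2.741537e-01,8.523441e+00
3.122958e-02,7.197461e+00,1.574353e-01,2.579220e-01,7.612819e+00
3.499636e-02,5.151909e+00,1.569571e-01,2.163701e-01,5.525237e+00
3.921746e-02,3.678523e+00,1.560889e-01,1.808127e-01,4.015425e+00
4.000000e-02,3.469125e+00,1.559002e-01,1.751996e-01,3.800224e+00
4.394769e-02,2.621322e+00,1.548526e-01,1.505278e-01,2.926702e+00
4.924846e-02,1.863578e+00,1.532691e-01,1.248565e-01,2.141704e+00
5.000000e-02,1.780666e+00,1.530335e-01,1.217572e-01,2.055456e+00
5.518859e-02,1.322317e+00,1.513589e-01,1.031998e-01,1.576876e+00
6.000000e-02,1.026551e+00,1.497603e-01,8.954196e-02,1.265853e+00
6.184519e-02,9.363128e-01,1.491418e-01,8.501593e-02,1.170471e+00
6.930468e-02,6.618435e-01,1.466380e-01,6.981767e-02,8.782992e-01
7.611000e-02,4.969782e-01,1.443784e-01,5.924609e-02,7.006027e-01
7.611200e-02,4.969382e-01,1.443777e-01,5.924334e-02,7.005593e-01
7.766389e-02,4.671314e-01,1.438683e-01,5.716981e-02,6.681696e-01
8.000000e-02,4.265465e-01,1.431066e-01,5.424778e-02,6.239008e-01
8.703136e-02,3.292398e-01,1.408541e-01,4.668699e-02,5.167809e-01
9.752869e-02,2.317169e-01,1.376177e-01,3.803117e-02,4.073658e-01
1.000000e-01,2.144716e-01,1.368791e-01,3.634404e-02,3.876947e-01
1.092922e-01,1.628991e-01,1.341827e-01,3.090862e-02,3.279904e-01
1.224745e-01,1.144253e-01,1.305734e-01,2.506639e-02,2.700650e-01
1.372468e-01,8.035267e-02,1.268153e-01,2.028836e-02,2.274563e-01
1.500000e-01,6.099482e-02,1.237958e-01,1.718038e-02,2.019710e-01
1.538009e-01,5.643896e-02,1.229385e-01,1.639129e-02,1.957688e-01
1.723517e-01,3.962037e-02,1.189803e-01,1.322070e-02,1.718214e-01
1.931399e-01,2.785108e-02,1.149292e-01,1.064714e-02,1.534275e-01
2.000000e-01,2.501681e-02,1.136765e-01,9.960776e-03,1.486541e-01
2.164356e-01,1.964092e-02,1.108283e-01,8.562668e-03,1.390319e-01
2.425411e-01,1.388006e-02,1.067008e-01,6.877653e-03,1.274586e-01
2.717953e-01,9.833883e-03,1.025682e-01,5.518000e-03,1.179201e-01
3.000000e-01,7.315009e-03,9.899603e-02,4.555007e-03,1.108660e-01
3.045780e-01,6.991188e-03,9.844975e-02,4.422681e-03,1.098636e-01
3.413149e-01,4.979688e-03,9.436238e-02,3.541612e-03,1.028837e-01
3.824827e-01,3.584034e-03,9.032072e-02,2.833828e-03,9.673858e-02
4.000000e-01,3.161674e-03,8.874665e-02,2.595450e-03,9.450377e-02
4.286161e-01,2.616840e-03,8.633694e-02,2.265922e-03,9.121970e-02
4.803138e-01,1.943807e-03,8.242091e-02,1.810730e-03,8.617544e-02
5.000000e-01,1.760782e-03,8.105729e-02,1.672802e-03,8.449087e-02
5.382471e-01,1.481850e-03,7.858047e-02,1.446219e-03,8.150854e-02
6.000000e-01,1.181071e-03,7.499369e-02,1.166660e-03,7.734142e-02
6.031680e-01,1.169360e-03,7.482175e-02,1.154561e-03,7.714567e-02
6.759194e-01,9.618402e-04,7.114948e-02,9.213617e-04,7.303268e-02
7.574458e-01,8.410887e-04,6.756738e-02,7.350174e-04,6.914348e-02
8.000000e-01,8.149498e-04,6.588096e-02,6.594017e-04,6.735531e-02
8.488055e-01,8.075502e-04,6.407846e-02,5.861931e-04,6.547221e-02
9.511845e-01,8.868612e-04,6.068530e-02,4.673884e-04,6.203955e-02
1.000000e+00,9.866369e-04,5.922496e-02,4.230777e-04,6.063467e-02
1.065912e+00,1.197295e-03,5.739020e-02,3.725850e-04,5.896008e-02
1.194478e+00,1.985177e-03,5.419535e-02,2.969592e-04,5.647748e-02
1.250000e+00,2.586406e-03,5.294913e-02,2.712488e-04,5.580678e-02
1.338550e+00,4.167788e-03,5.110285e-02,2.366488e-04,5.550729e-02
1.500000e+00,1.112617e-02,4.811476e-02,1.885636e-04,5.942950e-02
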