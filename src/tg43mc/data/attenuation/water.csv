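# per-process mass attenuation for water, cm^2/g
energy_MeV,mu_photoelectric,mu_incoherent,mu_coherent,mu_total,mu_en
1.000000e-02,4.927120e+00,1.851767e-01,2.167031e-01,5.329000e+00,4.944000e+00
1.500000e-02,1.354366e+00,1.936634e-01,1.249706e-01,1.673000e+00,1.374000e+00
2.000000e-02,5.319822e-01,1.957283e-01,8.188947e-02,8.096000e-01,5.503000e-01
3.000000e-02,1.383611e-01,1.939748e-01,4.326405e-02,3.756000e-01,1.557000e-01
4.000000e-02,5.168160e-02,1.898694e-01,2.674898e-02,2.683000e-01,6.947000e-02
5.000000e-02,2.350515e-02,1.852314e-01,1.816342e-02,2.269000e-01,4.223000e-02
6.000000e-02,1.218246e-02,1.805838e-01,1.313372e-02,2.059000e-01,3.190000e-02
8.000000e-02,4.111807e-03,1.718114e-01,7.776756e-03,1.837000e-01,2.597000e-02
1.000000e-01,1.611769e-03,1.639551e-01,5.133113e-03,1.707000e-01,2.546000e-02
1.500000e-01,2.060624e-04,1.479192e-01,2.374689e-03,1.505000e-01,2.764000e-02
2.000000e-01,1.000000e-08,1.356429e-01,1.361045e-03,1.370040e-01,2.967000e-02
3.000000e-01,1.000000e-08,1.180104e-01,6.152240e-04,1.186256e-01,3.192000e-02
4.000000e-01,1.000000e-08,1.057532e-01,3.486149e-04,1.061018e-01,3.279000e-02
5.000000e-01,7.243430e-05,9.657358e-02,2.239857e-04,9.687000e-02,3.299000e-02
6.000000e-01,6.325714e-05,8.934083e-02,1.559100e-04,8.956000e-02,3.284000e-02
8.000000e-01,8.489074e-05,7.847718e-02,8.792521e-05,7.865000e-02,3.206000e-02
1.000000e+00,1.183332e-04,7.054532e-02,5.634663e-05,7.072000e-02,3.103000e-02
1.250000e+00,1.258726e-04,6.306803e-02,3.609504e-05,6.323000e-02,2.965000e-02
1.500000e+00,2.060237e-04,5.730890e-02,2.507945e-05,5.754000e-02,2.833000e-02
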