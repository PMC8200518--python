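theta_deg,r_0.4,r_0.6,r_0.8,r_1,r_1.5,r_2,r_3,r_4,r_5,r_6,r_8,r_10
0,0.687,0.666,0.639,0.627,0.618,0.626,0.660,0.674,0.660,0.709,0.756,0.762
1,0.688,0.660,0.635,0.627,0.619,0.628,0.659,0.680,0.694,0.715,0.749,0.780
2,0.691,0.651,0.617,0.628,0.632,0.637,0.666,0.689,0.709,0.725,0.757,0.790
3,0.692,0.646,0.634,0.629,0.645,0.651,0.681,0.705,0.728,0.738,0.771,0.793
4,0.694,0.653,0.645,0.646,0.657,0.666,0.689,0.706,0.726,0.748,0.775,0.796
5,0.697,0.668,0.660,0.672,0.670,0.681,0.702,0.725,0.746,0.755,0.782,0.800
6,0.709,0.683,0.665,0.666,0.684,0.693,0.715,0.738,0.749,0.760,0.792,0.814
7,0.719,0.694,0.693,0.684,0.698,0.705,0.726,0.743,0.760,0.772,0.795,0.818
8,0.726,0.705,0.703,0.695,0.712,0.719,0.739,0.756,0.771,0.787,0.802,0.823
9,0.740,0.720,0.712,0.718,0.726,0.736,0.751,0.766,0.782,0.794,0.815,0.833
10,0.749,0.732,0.727,0.727,0.741,0.748,0.764,0.780,0.796,0.803,0.824,0.840
15,0.811,0.797,0.793,0.798,0.800,0.806,0.818,0.823,0.834,0.847,0.857,0.873
20,0.858,0.847,0.850,0.844,0.849,0.853,0.862,0.868,0.876,0.879,0.889,0.899
30,0.919,0.912,0.906,0.912,0.911,0.913,0.916,0.919,0.928,0.926,0.932,0.936
40,0.949,0.952,0.948,0.941,0.948,0.949,0.952,0.954,0.959,0.955,0.957,0.962
50,0.970,0.973,0.976,0.976,0.971,0.971,0.972,0.974,0.976,0.976,0.975,0.978
60,0.985,0.987,0.987,0.983,0.985,0.985,0.986,0.986,0.984,0.987,0.989,0.988
70,0.987,0.995,0.995,0.992,0.993,0.994,0.997,0.996,0.997,0.995,0.994,0.994
80,0.996,1.001,0.998,0.997,0.998,0.998,1.000,1.000,0.996,0.998,0.998,0.998
90,1,1,1,1,1,1,1,1,1,1,1,1
100,0.996,1.000,0.997,0.995,0.999,0.998,0.999,0.999,1.000,0.998,0.997,0.999
110,0.989,0.997,0.992,0.990,0.995,0.997,0.995,0.993,0.996,0.995,0.993,0.994
120,0.984,0.987,0.986,0.985,0.987,0.985,0.986,0.986,0.986,0.987,0.987,0.988
130,0.969,0.973,0.968,0.978,0.970,0.970,0.972,0.973,0.971,0.973,0.975,0.978
140,0.952,0.952,0.945,0.945,0.946,0.947,0.950,0.951,0.952,0.955,0.959,0.962
150,0.917,0.914,0.911,0.911,0.909,0.914,0.918,0.916,0.923,0.925,0.931,0.933
160,0.857,0.849,0.844,0.845,0.846,0.853,0.860,0.866,0.872,0.876,0.886,0.896
165,0.812,0.799,0.792,0.789,0.797,0.803,0.816,0.823,0.836,0.840,0.856,0.866
170,0.756,0.728,0.720,0.709,0.723,0.732,0.750,0.765,0.780,0.789,0.812,0.830
171,0.747,0.706,0.693,0.701,0.704,0.717,0.733,0.748,0.765,0.777,0.800,0.818
172,0.743,0.689,0.673,0.676,0.684,0.700,0.714,0.735,0.752,0.762,0.789,0.810
173,/,0.667,0.652,0.660,0.665,0.674,0.695,0.712,0.732,0.747,0.780,0.794
174,/,0.658,0.629,0.655,0.640,0.650,0.678,0.698,0.707,0.734,0.758,0.788
175,/,/,0.614,0.609,0.613,0.626,0.652,0.677,0.691,0.716,0.746,0.777
176,/,/,0.597,0.691,0.581,0.593,0.620,0.642,0.665,0.692,0.730,0.751
177,/,/,/,/,0.548,0.547,0.582,0.611,0.643,0.661,0.708,0.740
178,/,/,/,/,/,/,0.521,0.550,0.597,0.609,0.665,0.713
179,/,/,/,/,/,/,/,/,/,/,0.598,0.642
180,/,/,/,/,/,/,/,/,/,/,0.533,0.611
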