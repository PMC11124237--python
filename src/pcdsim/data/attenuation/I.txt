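# mass attenuation coefficients for I (Z=53, A=126.9045)
# photoelectric: Cromer-Liberman f'' (gemmi 0.7.4); incoherent: Klein-Nishina free-electron; coherent: Thomson x IT92 form factor
# K-edge: 33.169 keV
# columns: energy_keV photoelectric incoherent coherent total  [cm^2/g]
1.00000e+00 8.82378e+03 1.66662e-01 8.41742e+00 8.83237e+03
1.06619e+00 7.69293e+03 1.66619e-01 8.36210e+00 7.70146e+03
1.13675e+00 6.99839e+03 1.66574e-01 8.30084e+00 7.00686e+03
1.21199e+00 6.08166e+03 1.66525e-01 8.23319e+00 6.09006e+03
1.29220e+00 5.27704e+03 1.66473e-01 8.15873e+00 5.28536e+03
1.37773e+00 4.57197e+03 1.66418e-01 8.07707e+00 4.58021e+03
1.46892e+00 3.95454e+03 1.66359e-01 7.98787e+00 3.96270e+03
1.56614e+00 3.41300e+03 1.66296e-01 7.89084e+00 3.42105e+03
1.66979e+00 2.93989e+03 1.66230e-01 7.78576e+00 2.94784e+03
1.78031e+00 2.52897e+03 1.66159e-01 7.67249e+00 2.53681e+03
1.89814e+00 2.17271e+03 1.66083e-01 7.55099e+00 2.18043e+03
2.02377e+00 1.86431e+03 1.66002e-01 7.42132e+00 1.87189e+03
2.15771e+00 1.59769e+03 1.65916e-01 7.28366e+00 1.60514e+03
2.30052e+00 1.36744e+03 1.65825e-01 7.13826e+00 1.37474e+03
2.45279e+00 1.16901e+03 1.65728e-01 6.98550e+00 1.17617e+03
2.61512e+00 9.98106e+02 1.65624e-01 6.82580e+00 1.00510e+03
2.78821e+00 8.51323e+02 1.65514e-01 6.65968e+00 8.58148e+02
2.97275e+00 7.25453e+02 1.65396e-01 6.48766e+00 7.32107e+02
3.16950e+00 6.17052e+02 1.65271e-01 6.31032e+00 6.23528e+02
3.37928e+00 5.24450e+02 1.65138e-01 6.12819e+00 5.30744e+02
3.60294e+00 4.45382e+02 1.64997e-01 5.94182e+00 4.51489e+02
3.84140e+00 3.77854e+02 1.64847e-01 5.75168e+00 3.83770e+02
4.09564e+00 3.20338e+02 1.64687e-01 5.55820e+00 3.26061e+02
4.36672e+00 2.71440e+02 1.64517e-01 5.36178e+00 2.76967e+02
4.65573e+00 7.41858e+02 1.64336e-01 5.16275e+00 7.47185e+02
4.96387e+00 8.55829e+02 1.64143e-01 4.96144e+00 8.60955e+02
5.29241e+00 8.31686e+02 1.63939e-01 4.75821e+00 8.36609e+02
5.64269e+00 7.07240e+02 1.63722e-01 4.55351e+00 7.11957e+02
6.01616e+00 6.00601e+02 1.63491e-01 4.34792e+00 6.05113e+02
6.41434e+00 5.09287e+02 1.63246e-01 4.14218e+00 5.13593e+02
6.83888e+00 4.31324e+02 1.62986e-01 3.93720e+00 4.35424e+02
7.29151e+00 3.64913e+02 1.62710e-01 3.73407e+00 3.68809e+02
7.77410e+00 3.08439e+02 1.62417e-01 3.53394e+00 3.12135e+02
8.28864e+00 2.60465e+02 1.62106e-01 3.33801e+00 2.63965e+02
8.83723e+00 2.19751e+02 1.61776e-01 3.14739e+00 2.23061e+02
9.42212e+00 1.85158e+02 1.61426e-01 2.96304e+00 1.88282e+02
1.00457e+01 1.55862e+02 1.61056e-01 2.78570e+00 1.58808e+02
1.07106e+01 1.31097e+02 1.60663e-01 2.61583e+00 1.33873e+02
1.14195e+01 1.10198e+02 1.60247e-01 2.45363e+00 1.12812e+02
1.21753e+01 9.25837e+01 1.59806e-01 2.29899e+00 9.50425e+01
1.29811e+01 7.77470e+01 1.59340e-01 2.15161e+00 8.00580e+01
1.38403e+01 6.52569e+01 1.58847e-01 2.01101e+00 6.74268e+01
1.47563e+01 5.47473e+01 1.58326e-01 1.87665e+00 5.67823e+01
1.57330e+01 4.59084e+01 1.57776e-01 1.74802e+00 4.78142e+01
1.67743e+01 3.84774e+01 1.57194e-01 1.62469e+00 4.02593e+01
1.78845e+01 3.22323e+01 1.56580e-01 1.50640e+00 3.38953e+01
1.90682e+01 2.69877e+01 1.55933e-01 1.39303e+00 2.85366e+01
2.03302e+01 2.25847e+01 1.55250e-01 1.28461e+00 2.40245e+01
2.16758e+01 1.88898e+01 1.54531e-01 1.18127e+00 2.02256e+01
2.31104e+01 1.57920e+01 1.53774e-01 1.08324e+00 1.70290e+01
2.46400e+01 1.31974e+01 1.52978e-01 9.90746e-01 1.43412e+01
2.62708e+01 1.10260e+01 1.52142e-01 9.01685e-01 1.20798e+01
2.80096e+01 9.19559e+00 1.51263e-01 8.15646e-01 1.01625e+01
2.98634e+01 7.66452e+00 1.50341e-01 7.35337e-01 8.55020e+00
3.18400e+01 6.38782e+00 1.49375e-01 6.61697e-01 7.19889e+00
3.31358e+01 5.70257e+00 1.48750e-01 6.19263e-01 6.47059e+00
3.32022e+01 3.50929e+01 1.48719e-01 6.17203e-01 3.58588e+01
3.39473e+01 3.31041e+01 1.48363e-01 5.94765e-01 3.38472e+01
3.61941e+01 2.79740e+01 1.47304e-01 5.34176e-01 2.86554e+01
3.85897e+01 2.36243e+01 1.46198e-01 4.79412e-01 2.42499e+01
4.11437e+01 1.99315e+01 1.45043e-01 4.29938e-01 2.05064e+01
4.38669e+01 1.67980e+01 1.43838e-01 3.85245e-01 1.73271e+01
4.67702e+01 1.41409e+01 1.42584e-01 3.44877e-01 1.46284e+01
4.98657e+01 1.18933e+01 1.41279e-01 3.08429e-01 1.23430e+01
5.31661e+01 9.99365e+00 1.39923e-01 2.75543e-01 1.04091e+01
5.66850e+01 8.38966e+00 1.38517e-01 2.45897e-01 8.77407e+00
6.04367e+01 7.03652e+00 1.37060e-01 2.19204e-01 7.39279e+00
6.44367e+01 5.89608e+00 1.35552e-01 1.95201e-01 6.22683e+00
6.87015e+01 4.93480e+00 1.33995e-01 1.73646e-01 5.24244e+00
7.32486e+01 4.12662e+00 1.32389e-01 1.54320e-01 4.41333e+00
7.80966e+01 3.44857e+00 1.30735e-01 1.37016e-01 3.71632e+00
8.32654e+01 2.87537e+00 1.29034e-01 1.21547e-01 3.12595e+00
8.87764e+01 2.39472e+00 1.27287e-01 1.07736e-01 2.62974e+00
9.46521e+01 1.99433e+00 1.25498e-01 9.54224e-02 2.21525e+00
1.00917e+02 1.66080e+00 1.23666e-01 8.44579e-02 1.86893e+00
1.07596e+02 1.38299e+00 1.21796e-01 7.47060e-02 1.57950e+00
1.14717e+02 1.15160e+00 1.19889e-01 6.60420e-02 1.33753e+00
1.22310e+02 9.58873e-01 1.17947e-01 5.83523e-02 1.13517e+00
1.30405e+02 7.98359e-01 1.15974e-01 5.15335e-02 9.65867e-01
1.39036e+02 6.64680e-01 1.13973e-01 4.54922e-02 8.24145e-01
1.48238e+02 5.53356e-01 1.11946e-01 4.01437e-02 7.05445e-01
1.58049e+02 4.60652e-01 1.09897e-01 3.54118e-02 6.05960e-01
1.68510e+02 3.83458e-01 1.07829e-01 3.12280e-02 5.22515e-01
1.79663e+02 3.19183e-01 1.05746e-01 2.75309e-02 4.52459e-01
1.91554e+02 2.65667e-01 1.03650e-01 2.42655e-02 3.93582e-01
2.04232e+02 2.21112e-01 1.01545e-01 2.13828e-02 3.44040e-01
2.17749e+02 1.84020e-01 9.94336e-02 1.88388e-02 3.02293e-01
2.32161e+02 1.53143e-01 9.73199e-02 1.65946e-02 2.67057e-01
2.47527e+02 1.27440e-01 9.52064e-02 1.46155e-02 2.37262e-01
2.63910e+02 1.06046e-01 9.30960e-02 1.28706e-02 2.12013e-01
2.81377e+02 8.82396e-02 9.09914e-02 1.13327e-02 1.90564e-01
3.00000e+02 7.34198e-02 8.88952e-02 9.97745e-03 1.72292e-01
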