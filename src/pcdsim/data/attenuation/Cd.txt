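# mass attenuation coefficients for Cd (Z=48, A=112.4110)
# photoelectric: Cromer-Liberman f'' (gemmi 0.7.4); incoherent: Klein-Nishina free-electron; coherent: Thomson x IT92 form factor
# K-edge: 26.711 keV
# columns: energy_keV photoelectric incoherent coherent total  [cm^2/g]
1.00000e+00 7.10294e+03 1.70401e-01 7.82594e+00 7.11093e+03
1.06619e+00 6.16692e+03 1.70357e-01 7.77894e+00 6.17486e+03
1.13675e+00 5.34158e+03 1.70310e-01 7.72692e+00 5.34948e+03
1.21199e+00 4.61914e+03 1.70260e-01 7.66950e+00 4.62698e+03
1.29220e+00 3.98918e+03 1.70207e-01 7.60629e+00 3.99696e+03
1.37773e+00 3.44002e+03 1.70151e-01 7.53695e+00 3.44772e+03
1.46892e+00 2.96266e+03 1.70091e-01 7.46112e+00 2.97029e+03
1.56614e+00 2.54841e+03 1.70026e-01 7.37848e+00 2.55596e+03
1.66979e+00 2.18864e+03 1.69958e-01 7.28873e+00 2.19610e+03
1.78031e+00 1.87675e+03 1.69885e-01 7.19160e+00 1.88412e+03
1.89814e+00 1.60782e+03 1.69808e-01 7.08686e+00 1.61507e+03
2.02377e+00 1.37613e+03 1.69726e-01 6.97432e+00 1.38327e+03
2.15771e+00 1.17671e+03 1.69638e-01 6.85382e+00 1.18374e+03
2.30052e+00 1.00522e+03 1.69544e-01 6.72524e+00 1.01212e+03
2.45279e+00 8.57884e+02 1.69445e-01 6.58851e+00 8.64642e+02
2.61512e+00 7.31291e+02 1.69339e-01 6.44363e+00 7.37904e+02
2.78821e+00 6.22795e+02 1.69226e-01 6.29068e+00 6.29255e+02
2.97275e+00 5.29986e+02 1.69106e-01 6.12980e+00 5.36285e+02
3.16950e+00 4.50013e+02 1.68978e-01 5.96127e+00 4.56143e+02
3.37928e+00 3.81804e+02 1.68842e-01 5.78549e+00 3.87759e+02
3.60294e+00 1.09213e+03 1.68698e-01 5.60300e+00 1.09790e+03
3.84140e+00 1.28353e+03 1.68544e-01 5.41447e+00 1.28912e+03
4.09564e+00 1.25397e+03 1.68381e-01 5.22071e+00 1.25936e+03
4.36672e+00 1.06741e+03 1.68207e-01 5.02266e+00 1.07260e+03
4.65573e+00 9.07606e+02 1.68022e-01 4.82136e+00 9.12595e+02
4.96387e+00 7.70459e+02 1.67825e-01 4.61792e+00 7.75245e+02
5.29241e+00 6.53194e+02 1.67616e-01 4.41354e+00 6.57775e+02
5.64269e+00 5.53116e+02 1.67394e-01 4.20943e+00 5.57493e+02
6.01616e+00 4.67926e+02 1.67158e-01 4.00684e+00 4.72100e+02
6.41434e+00 3.95485e+02 1.66908e-01 3.80698e+00 3.99459e+02
6.83888e+00 3.33948e+02 1.66642e-01 3.61100e+00 3.37725e+02
7.29151e+00 2.81709e+02 1.66360e-01 3.41993e+00 2.85296e+02
7.77410e+00 2.37414e+02 1.66060e-01 3.23460e+00 2.40815e+02
8.28864e+00 1.99924e+02 1.65742e-01 3.05562e+00 2.03146e+02
8.83723e+00 1.68234e+02 1.65405e-01 2.88332e+00 1.71283e+02
9.42212e+00 1.41361e+02 1.65047e-01 2.71777e+00 1.44243e+02
1.00457e+01 1.18713e+02 1.64668e-01 2.55878e+00 1.21436e+02
1.07106e+01 9.96479e+01 1.64266e-01 2.40596e+00 1.02218e+02
1.14195e+01 8.36072e+01 1.63841e-01 2.25884e+00 8.60299e+01
1.21753e+01 7.01120e+01 1.63391e-01 2.11691e+00 7.23923e+01
1.29811e+01 5.87640e+01 1.62914e-01 1.97976e+00 6.09067e+01
1.38403e+01 4.92318e+01 1.62410e-01 1.84710e+00 5.12413e+01
1.47563e+01 4.12284e+01 1.61877e-01 1.71885e+00 4.31091e+01
1.57330e+01 3.45077e+01 1.61314e-01 1.59506e+00 3.62641e+01
1.67743e+01 2.88631e+01 1.60720e-01 1.47596e+00 3.04997e+01
1.78845e+01 2.41288e+01 1.60092e-01 1.36188e+00 2.56508e+01
1.90682e+01 2.01625e+01 1.59430e-01 1.25319e+00 2.15751e+01
2.03302e+01 1.68439e+01 1.58732e-01 1.15028e+00 1.81530e+01
2.16758e+01 1.40680e+01 1.57997e-01 1.05347e+00 1.52794e+01
2.31104e+01 1.17463e+01 1.57224e-01 9.63009e-01 1.28666e+01
2.46400e+01 9.80502e+00 1.56410e-01 8.79024e-01 1.08405e+01
2.62708e+01 8.18210e+00 1.55554e-01 7.99230e-01 9.13688e+00
2.66843e+01 7.82883e+00 1.55339e-01 7.80145e-01 8.76431e+00
2.67377e+01 5.03181e+01 1.55312e-01 7.77717e-01 5.12511e+01
2.80096e+01 4.43362e+01 1.54656e-01 7.22538e-01 4.52134e+01
2.98634e+01 3.74720e+01 1.53713e-01 6.51069e-01 3.82768e+01
3.18400e+01 3.16395e+01 1.52725e-01 5.85548e-01 3.23778e+01
3.39473e+01 2.66869e+01 1.51691e-01 5.25979e-01 2.73646e+01
3.61941e+01 2.24774e+01 1.50608e-01 4.72041e-01 2.31000e+01
3.85897e+01 1.89108e+01 1.49477e-01 4.23289e-01 1.94835e+01
4.11437e+01 1.58959e+01 1.48296e-01 3.79259e-01 1.64234e+01
4.38669e+01 1.33497e+01 1.47064e-01 3.39510e-01 1.38363e+01
4.67702e+01 1.12012e+01 1.45782e-01 3.03641e-01 1.16506e+01
4.98657e+01 9.38991e+00 1.44448e-01 2.71291e-01 9.80565e+00
5.31661e+01 7.86430e+00 1.43062e-01 2.42139e-01 8.24950e+00
5.66850e+01 6.57585e+00 1.41624e-01 2.15894e-01 6.93337e+00
6.04367e+01 5.49456e+00 1.40134e-01 1.92295e-01 5.82699e+00
6.44367e+01 4.58808e+00 1.38593e-01 1.71103e-01 4.89778e+00
6.87015e+01 3.82864e+00 1.37001e-01 1.52097e-01 4.11774e+00
7.32486e+01 3.19280e+00 1.35358e-01 1.35077e-01 3.46323e+00
7.80966e+01 2.66079e+00 1.33667e-01 1.19857e-01 2.91431e+00
8.32654e+01 2.21393e+00 1.31928e-01 1.06264e-01 2.45212e+00
8.87764e+01 1.84072e+00 1.30142e-01 9.41411e-02 2.06500e+00
9.46521e+01 1.53026e+00 1.28313e-01 8.33425e-02 1.74192e+00
1.00917e+02 1.27203e+00 1.26440e-01 7.37348e-02 1.47220e+00
1.07596e+02 1.05725e+00 1.24528e-01 6.51962e-02 1.24698e+00
1.14717e+02 8.78642e-01 1.22578e-01 5.76155e-02 1.05884e+00
1.22310e+02 7.30122e-01 1.20593e-01 5.08913e-02 9.01606e-01
1.30405e+02 6.06636e-01 1.18575e-01 4.49321e-02 7.70144e-01
1.39036e+02 5.03976e-01 1.16529e-01 3.96550e-02 6.60160e-01
1.48238e+02 4.18639e-01 1.14457e-01 3.49851e-02 5.68081e-01
1.58049e+02 3.47710e-01 1.12362e-01 3.08553e-02 4.90927e-01
1.68510e+02 2.88763e-01 1.10248e-01 2.72051e-02 4.26216e-01
1.79663e+02 2.39780e-01 1.08117e-01 2.39807e-02 3.71878e-01
1.91554e+02 1.99082e-01 1.05974e-01 2.11335e-02 3.26190e-01
2.04232e+02 1.65271e-01 1.03822e-01 1.86206e-02 2.87713e-01
2.17749e+02 1.37185e-01 1.01664e-01 1.64034e-02 2.55252e-01
2.32161e+02 1.13858e-01 9.95028e-02 1.44480e-02 2.27809e-01
2.47527e+02 9.44863e-02 9.73419e-02 1.27238e-02 2.04552e-01
2.63910e+02 7.84006e-02 9.51841e-02 1.12040e-02 1.84789e-01
2.81377e+02 6.50455e-02 9.30323e-02 9.86452e-03 1.67942e-01
3.00000e+02 5.39588e-02 9.08891e-02 8.68436e-03 1.53532e-01
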