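# mass attenuation coefficients for Cu (Z=29, A=63.5460)
# photoelectric: Cromer-Liberman f'' (gemmi 0.7.4); incoherent: Klein-Nishina free-electron; coherent: Thomson x IT92 form factor
# K-edge: 8.979 keV
# columns: energy_keV photoelectric incoherent coherent total  [cm^2/g]
1.00000e+00 1.05538e+04 1.82116e-01 5.05630e+00 1.05590e+04
1.06619e+00 8.75593e+03 1.82069e-01 5.02661e+00 8.76114e+03
1.13675e+00 8.45413e+03 1.82019e-01 4.99368e+00 8.45931e+03
1.21199e+00 7.28016e+03 1.81966e-01 4.95724e+00 7.28530e+03
1.29220e+00 6.23643e+03 1.81909e-01 4.91705e+00 6.24153e+03
1.37773e+00 5.33564e+03 1.81849e-01 4.87285e+00 5.34069e+03
1.46892e+00 4.55678e+03 1.81785e-01 4.82440e+00 4.56178e+03
1.56614e+00 3.88564e+03 1.81716e-01 4.77149e+00 3.89059e+03
1.66979e+00 3.30985e+03 1.81643e-01 4.71389e+00 3.31475e+03
1.78031e+00 2.81627e+03 1.81566e-01 4.65144e+00 2.82110e+03
1.89814e+00 2.39369e+03 1.81483e-01 4.58397e+00 2.39846e+03
2.02377e+00 2.03234e+03 1.81395e-01 4.51133e+00 2.03703e+03
2.15771e+00 1.72370e+03 1.81301e-01 4.43341e+00 1.72832e+03
2.30052e+00 1.46022e+03 1.81201e-01 4.35010e+00 1.46475e+03
2.45279e+00 1.23574e+03 1.81095e-01 4.26131e+00 1.24018e+03
2.61512e+00 1.04476e+03 1.80981e-01 4.16697e+00 1.04911e+03
2.78821e+00 8.82463e+02 1.80861e-01 4.06701e+00 8.86711e+02
2.97275e+00 7.44685e+02 1.80733e-01 3.96139e+00 7.48827e+02
3.16950e+00 6.27471e+02 1.80596e-01 3.85010e+00 6.31502e+02
3.37928e+00 5.28311e+02 1.80451e-01 3.73319e+00 5.32224e+02
3.60294e+00 4.44544e+02 1.80296e-01 3.61081e+00 4.48335e+02
3.84140e+00 3.73737e+02 1.80132e-01 3.48319e+00 3.77401e+02
4.09564e+00 3.13908e+02 1.79957e-01 3.35073e+00 3.17438e+02
4.36672e+00 2.63534e+02 1.79771e-01 3.21395e+00 2.66927e+02
4.65573e+00 2.21141e+02 1.79574e-01 3.07353e+00 2.24394e+02
4.96387e+00 1.85430e+02 1.79364e-01 2.93028e+00 1.88540e+02
5.29241e+00 1.55401e+02 1.79140e-01 2.78515e+00 1.58366e+02
5.64269e+00 1.30183e+02 1.78903e-01 2.63913e+00 1.33001e+02
6.01616e+00 1.09012e+02 1.78651e-01 2.49325e+00 1.11684e+02
6.41434e+00 9.12470e+01 1.78383e-01 2.34855e+00 9.37739e+01
6.83888e+00 7.63458e+01 1.78099e-01 2.20603e+00 7.87300e+01
7.29151e+00 6.38518e+01 1.77797e-01 2.06662e+00 6.60962e+01
7.77410e+00 5.33801e+01 1.77477e-01 1.93117e+00 5.54888e+01
8.28864e+00 4.46069e+01 1.77137e-01 1.80041e+00 4.65844e+01
8.83723e+00 3.72595e+01 1.76777e-01 1.67498e+00 3.91112e+01
8.97002e+00 3.57211e+01 1.76690e-01 1.64661e+00 3.75444e+01
8.98798e+00 2.86962e+02 1.76678e-01 1.64283e+00 2.88781e+02
9.42212e+00 2.49867e+02 1.76395e-01 1.55541e+00 2.51598e+02
1.00457e+01 2.11842e+02 1.75989e-01 1.44209e+00 2.13460e+02
1.07106e+01 1.79355e+02 1.75560e-01 1.33527e+00 1.80866e+02
1.14195e+01 1.51638e+02 1.75106e-01 1.23509e+00 1.53048e+02
1.21753e+01 1.27926e+02 1.74624e-01 1.14150e+00 1.29242e+02
1.29811e+01 1.07760e+02 1.74115e-01 1.05435e+00 1.08988e+02
1.38403e+01 9.06781e+01 1.73576e-01 9.73342e-01 9.18250e+01
1.47563e+01 7.62240e+01 1.73007e-01 8.98096e-01 7.72951e+01
1.57330e+01 6.40062e+01 1.72405e-01 8.28167e-01 6.50067e+01
1.67743e+01 5.36897e+01 1.71770e-01 7.63088e-01 5.46245e+01
1.78845e+01 4.49877e+01 1.71099e-01 7.02406e-01 4.58613e+01
1.90682e+01 3.76347e+01 1.70392e-01 6.45716e-01 3.84508e+01
2.03302e+01 3.14555e+01 1.69646e-01 5.92671e-01 3.22178e+01
2.16758e+01 2.62685e+01 1.68860e-01 5.42995e-01 2.69803e+01
2.31104e+01 2.19181e+01 1.68033e-01 4.96477e-01 2.25826e+01
2.46400e+01 1.82723e+01 1.67163e-01 4.52962e-01 1.88925e+01
2.62708e+01 1.52200e+01 1.66249e-01 4.11204e-01 1.57975e+01
2.80096e+01 1.26614e+01 1.65289e-01 3.70908e-01 1.31976e+01
2.98634e+01 1.05241e+01 1.64282e-01 3.33386e-01 1.10218e+01
3.18400e+01 8.74187e+00 1.63226e-01 2.99095e-01 9.20419e+00
3.39473e+01 7.25661e+00 1.62120e-01 2.68052e-01 7.68678e+00
3.61941e+01 6.01965e+00 1.60963e-01 2.40075e-01 6.42068e+00
3.85897e+01 4.99016e+00 1.59754e-01 2.14904e-01 5.36482e+00
4.11437e+01 4.12819e+00 1.58492e-01 1.92268e-01 4.47895e+00
4.38669e+01 3.41306e+00 1.57175e-01 1.71911e-01 3.74214e+00
4.67702e+01 2.82073e+00 1.55805e-01 1.53599e-01 3.13013e+00
4.98657e+01 2.33030e+00 1.54379e-01 1.37130e-01 2.62181e+00
5.31661e+01 1.92440e+00 1.52898e-01 1.22321e-01 2.19962e+00
5.66850e+01 1.58857e+00 1.51361e-01 1.09013e-01 1.84895e+00
6.04367e+01 1.31084e+00 1.49769e-01 9.70634e-02 1.55767e+00
6.44367e+01 1.08123e+00 1.48121e-01 8.63443e-02 1.31570e+00
6.87015e+01 8.91486e-01 1.46420e-01 7.67396e-02 1.11465e+00
7.32486e+01 7.34746e-01 1.44665e-01 6.81438e-02 9.47554e-01
7.80966e+01 6.05320e-01 1.42857e-01 6.04604e-02 8.08637e-01
8.32654e+01 4.98490e-01 1.40998e-01 5.36012e-02 6.93090e-01
8.87764e+01 4.10348e-01 1.39090e-01 4.74851e-02 5.96923e-01
9.46521e+01 3.37653e-01 1.37134e-01 4.20380e-02 5.16826e-01
1.00917e+02 2.77723e-01 1.35133e-01 3.71923e-02 4.50049e-01
1.07596e+02 2.28336e-01 1.33090e-01 3.28860e-02 3.94312e-01
1.14717e+02 1.87655e-01 1.31005e-01 2.90628e-02 3.47723e-01
1.22310e+02 1.54158e-01 1.28884e-01 2.56717e-02 3.08713e-01
1.30405e+02 1.26588e-01 1.26728e-01 2.26664e-02 2.75982e-01
1.39036e+02 1.03906e-01 1.24541e-01 2.00049e-02 2.48452e-01
1.48238e+02 8.52524e-02 1.22326e-01 1.76496e-02 2.25228e-01
1.58049e+02 6.99189e-02 1.20087e-01 1.55666e-02 2.05573e-01
1.68510e+02 5.73195e-02 1.17828e-01 1.37255e-02 1.88873e-01
1.79663e+02 4.69711e-02 1.15551e-01 1.20990e-02 1.74621e-01
1.91554e+02 3.84750e-02 1.13261e-01 1.06628e-02 1.62398e-01
2.04232e+02 3.15026e-02 1.10960e-01 9.39516e-03 1.51858e-01
2.17749e+02 2.57831e-02 1.08654e-01 8.27667e-03 1.42713e-01
2.32161e+02 2.10933e-02 1.06344e-01 7.29015e-03 1.34727e-01
2.47527e+02 1.72494e-02 1.04034e-01 6.42027e-03 1.27704e-01
2.63910e+02 1.41002e-02 1.01728e-01 5.65347e-03 1.21482e-01
2.81377e+02 1.15212e-02 9.94286e-02 4.97767e-03 1.15927e-01
3.00000e+02 9.41000e-03 9.71380e-02 4.38221e-03 1.10930e-01
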