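# mass attenuation coefficients for C (Z=6, A=12.0107)
# photoelectric: Cromer-Liberman f'' (gemmi 0.7.4); incoherent: Klein-Nishina free-electron; coherent: Thomson x IT92 form factor
# K-edge: none keV
# columns: energy_keV photoelectric incoherent coherent total  [cm^2/g]
1.00000e+00 2.07258e+03 1.99352e-01 1.07892e+00 2.07385e+03
1.06619e+00 1.73306e+03 1.99301e-01 1.06424e+00 1.73432e+03
1.13675e+00 1.44774e+03 1.99246e-01 1.04806e+00 1.44899e+03
1.21199e+00 1.20676e+03 1.99188e-01 1.03027e+00 1.20799e+03
1.29220e+00 1.00511e+03 1.99126e-01 1.01082e+00 1.00632e+03
1.37773e+00 8.36503e+02 1.99060e-01 9.89620e-01 8.37692e+02
1.46892e+00 6.95643e+02 1.98990e-01 9.66648e-01 6.96808e+02
1.56614e+00 5.78053e+02 1.98915e-01 9.41883e-01 5.79194e+02
1.66979e+00 4.79967e+02 1.98835e-01 9.15340e-01 4.81081e+02
1.78031e+00 3.98216e+02 1.98750e-01 8.87071e-01 3.99301e+02
1.89814e+00 3.30132e+02 1.98659e-01 8.57167e-01 3.31188e+02
2.02377e+00 2.73476e+02 1.98563e-01 8.25756e-01 2.74500e+02
2.15771e+00 2.26367e+02 1.98460e-01 7.93013e-01 2.27358e+02
2.30052e+00 1.87227e+02 1.98351e-01 7.59146e-01 1.88185e+02
2.45279e+00 1.54734e+02 1.98234e-01 7.24400e-01 1.55657e+02
2.61512e+00 1.27781e+02 1.98110e-01 6.89048e-01 1.28668e+02
2.78821e+00 1.05441e+02 1.97978e-01 6.53378e-01 1.06292e+02
2.97275e+00 8.69387e+01 1.97838e-01 6.17689e-01 8.77542e+01
3.16950e+00 7.15931e+01 1.97689e-01 5.82276e-01 7.23731e+01
3.37928e+00 5.89126e+01 1.97530e-01 5.47422e-01 5.96576e+01
3.60294e+00 4.84465e+01 1.97360e-01 5.13390e-01 4.91573e+01
3.84140e+00 3.98138e+01 1.97181e-01 4.80412e-01 4.04914e+01
4.09564e+00 3.26981e+01 1.96989e-01 4.48687e-01 3.33438e+01
4.36672e+00 2.68366e+01 1.96786e-01 4.18377e-01 2.74518e+01
4.65573e+00 2.20115e+01 1.96569e-01 3.89602e-01 2.25977e+01
4.96387e+00 1.80422e+01 1.96339e-01 3.62440e-01 1.86010e+01
5.29241e+00 1.47790e+01 1.96095e-01 3.36931e-01 1.53120e+01
5.64269e+00 1.20911e+01 1.95835e-01 3.13075e-01 1.26000e+01
6.01616e+00 9.88665e+00 1.95559e-01 2.90841e-01 1.03731e+01
6.41434e+00 8.08031e+00 1.95266e-01 2.70168e-01 8.54574e+00
6.83888e+00 6.60089e+00 1.94955e-01 2.50976e-01 7.04682e+00
7.29151e+00 5.38980e+00 1.94625e-01 2.33167e-01 5.81760e+00
7.77410e+00 4.39885e+00 1.94274e-01 2.16636e-01 4.80976e+00
8.28864e+00 3.58841e+00 1.93902e-01 2.01277e-01 3.98359e+00
8.83723e+00 2.92590e+00 1.93508e-01 1.86979e-01 3.30639e+00
9.42212e+00 2.38078e+00 1.93089e-01 1.73638e-01 2.74751e+00
1.00457e+01 1.93637e+00 1.92646e-01 1.61155e-01 2.29017e+00
1.07106e+01 1.57455e+00 1.92176e-01 1.49441e-01 1.91617e+00
1.14195e+01 1.28005e+00 1.91678e-01 1.38416e-01 1.61014e+00
1.21753e+01 1.04039e+00 1.91152e-01 1.28015e-01 1.35956e+00
1.29811e+01 8.45410e-01 1.90594e-01 1.18183e-01 1.15419e+00
1.38403e+01 6.86814e-01 1.90005e-01 1.08880e-01 9.85699e-01
1.47563e+01 5.57843e-01 1.89381e-01 1.00077e-01 8.47301e-01
1.57330e+01 4.52986e-01 1.88722e-01 9.17550e-02 7.33464e-01
1.67743e+01 3.67755e-01 1.88027e-01 8.39051e-02 6.39687e-01
1.78845e+01 2.98493e-01 1.87293e-01 7.65237e-02 5.62309e-01
1.90682e+01 2.42219e-01 1.86518e-01 6.96114e-02 4.98349e-01
2.03302e+01 1.96510e-01 1.85702e-01 6.31697e-02 4.45382e-01
2.16758e+01 1.59390e-01 1.84842e-01 5.71985e-02 4.01431e-01
2.31104e+01 1.29253e-01 1.83937e-01 5.16938e-02 3.64883e-01
2.46400e+01 1.04789e-01 1.82984e-01 4.66458e-02 3.34420e-01
2.62708e+01 8.49369e-02 1.81984e-01 4.20012e-02 3.08922e-01
2.80096e+01 6.87068e-02 1.80933e-01 3.77255e-02 2.87365e-01
2.98634e+01 5.55460e-02 1.79830e-01 3.38320e-02 2.69208e-01
3.18400e+01 4.49090e-02 1.78674e-01 3.03070e-02 2.53890e-01
3.39473e+01 3.63114e-02 1.77464e-01 2.71253e-02 2.40900e-01
3.61941e+01 2.93616e-02 1.76197e-01 2.42579e-02 2.29817e-01
3.85897e+01 2.37435e-02 1.74874e-01 2.16760e-02 2.20293e-01
4.11437e+01 1.92016e-02 1.73492e-01 1.93527e-02 2.12046e-01
4.38669e+01 1.55295e-02 1.72051e-01 1.72633e-02 2.04844e-01
4.67702e+01 1.25604e-02 1.70551e-01 1.53857e-02 1.98497e-01
4.98657e+01 1.01597e-02 1.68990e-01 1.36998e-02 1.92849e-01
5.31661e+01 8.21831e-03 1.67368e-01 1.21876e-02 1.87774e-01
5.66850e+01 6.64833e-03 1.65686e-01 1.08326e-02 1.83167e-01
6.04367e+01 5.37862e-03 1.63943e-01 9.62003e-03 1.78942e-01
6.44367e+01 4.35167e-03 1.62140e-01 8.53613e-03 1.75028e-01
6.87015e+01 3.52102e-03 1.60278e-01 7.56844e-03 1.71367e-01
7.32486e+01 2.84910e-03 1.58356e-01 6.70552e-03 1.67911e-01
7.80966e+01 2.30555e-03 1.56378e-01 5.93692e-03 1.64620e-01
8.32654e+01 1.86581e-03 1.54343e-01 5.25308e-03 1.61462e-01
8.87764e+01 1.51004e-03 1.52254e-01 4.64530e-03 1.58410e-01
9.46521e+01 1.22219e-03 1.50113e-01 4.10564e-03 1.55441e-01
1.00917e+02 9.89265e-04 1.47923e-01 3.62690e-03 1.52539e-01
1.07596e+02 8.00783e-04 1.45686e-01 3.20256e-03 1.49689e-01
1.14717e+02 6.48253e-04 1.43404e-01 2.82674e-03 1.46879e-01
1.22310e+02 5.24808e-04 1.41082e-01 2.49411e-03 1.44101e-01
1.30405e+02 4.24897e-04 1.38722e-01 2.19990e-03 1.41347e-01
1.39036e+02 3.44028e-04 1.36328e-01 1.93982e-03 1.38612e-01
1.48238e+02 2.78568e-04 1.33904e-01 1.71004e-03 1.35892e-01
1.58049e+02 2.25577e-04 1.31453e-01 1.50713e-03 1.33186e-01
1.68510e+02 1.82678e-04 1.28979e-01 1.32801e-03 1.30490e-01
1.79663e+02 1.47946e-04 1.26487e-01 1.16996e-03 1.27805e-01
1.91554e+02 1.19825e-04 1.23980e-01 1.03054e-03 1.25130e-01
2.04232e+02 9.70554e-05 1.21462e-01 9.07603e-04 1.22467e-01
2.17749e+02 7.86173e-05 1.18937e-01 7.99225e-04 1.19815e-01
2.32161e+02 6.36860e-05 1.16409e-01 7.03705e-04 1.17176e-01
2.47527e+02 5.15936e-05 1.13881e-01 6.19536e-04 1.14552e-01
2.63910e+02 4.17999e-05 1.11356e-01 5.45384e-04 1.11944e-01
2.81377e+02 3.38674e-05 1.08839e-01 4.80066e-04 1.09353e-01
3.00000e+02 2.74420e-05 1.06332e-01 4.22541e-04 1.06782e-01
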