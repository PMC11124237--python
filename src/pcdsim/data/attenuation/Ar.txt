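# mass attenuation coefficients for Ar (Z=18, A=39.9480)
# photoelectric: Cromer-Liberman f'' (gemmi 0.7.4); incoherent: Klein-Nishina free-electron; coherent: Thomson x IT92 form factor
# K-edge: none keV
# columns: energy_keV photoelectric incoherent coherent total  [cm^2/g]
1.00000e+00 3.05604e+03 1.79811e-01 3.04133e+00 3.05926e+03
1.06619e+00 2.58768e+03 1.79765e-01 3.01529e+00 2.59088e+03
1.13675e+00 2.18960e+03 1.79715e-01 2.98632e+00 2.19276e+03
1.21199e+00 1.85149e+03 1.79663e-01 2.95417e+00 1.85463e+03
1.29220e+00 1.56445e+03 1.79607e-01 2.91861e+00 1.56755e+03
1.37773e+00 1.32058e+03 1.79547e-01 2.87940e+00 1.32364e+03
1.46892e+00 1.11404e+03 1.79484e-01 2.83633e+00 1.11705e+03
1.56614e+00 9.39232e+02 1.79416e-01 2.78921e+00 9.42201e+02
1.66979e+00 7.91385e+02 1.79344e-01 2.73789e+00 7.94302e+02
1.78031e+00 6.66421e+02 1.79267e-01 2.68227e+00 6.69282e+02
1.89814e+00 5.60865e+02 1.79186e-01 2.62231e+00 5.63666e+02
2.02377e+00 4.71757e+02 1.79099e-01 2.55805e+00 4.74494e+02
2.15771e+00 3.96581e+02 1.79006e-01 2.48960e+00 3.99249e+02
2.30052e+00 3.33194e+02 1.78907e-01 2.41717e+00 3.35790e+02
2.45279e+00 2.79780e+02 1.78802e-01 2.34105e+00 2.82300e+02
2.61512e+00 2.34794e+02 1.78691e-01 2.26165e+00 2.37234e+02
2.78821e+00 1.96928e+02 1.78572e-01 2.17945e+00 1.99286e+02
2.97275e+00 1.65072e+02 1.78445e-01 2.09503e+00 1.67346e+02
3.16950e+00 1.38174e+02 1.78310e-01 2.00900e+00 1.40361e+02
3.37928e+00 1.17205e+03 1.78167e-01 1.92203e+00 1.17415e+03
3.60294e+00 9.93827e+02 1.78014e-01 1.83483e+00 9.95840e+02
3.84140e+00 8.41788e+02 1.77852e-01 1.74807e+00 8.43714e+02
4.09564e+00 7.12229e+02 1.77679e-01 1.66239e+00 7.14070e+02
4.36672e+00 6.02067e+02 1.77496e-01 1.57841e+00 6.03823e+02
4.65573e+00 5.08376e+02 1.77301e-01 1.49664e+00 5.10049e+02
4.96387e+00 4.28738e+02 1.77093e-01 1.41751e+00 4.30333e+02
5.29241e+00 3.61148e+02 1.76873e-01 1.34133e+00 3.62666e+02
5.64269e+00 3.03852e+02 1.76639e-01 1.26832e+00 3.05297e+02
6.01616e+00 2.55339e+02 1.76390e-01 1.19856e+00 2.56714e+02
6.41434e+00 2.14303e+02 1.76125e-01 1.13201e+00 2.15611e+02
6.83888e+00 1.79562e+02 1.75845e-01 1.06852e+00 1.80807e+02
7.29151e+00 1.50310e+02 1.75547e-01 1.00788e+00 1.51494e+02
7.77410e+00 1.25704e+02 1.75230e-01 9.49782e-01 1.26829e+02
8.28864e+00 1.05025e+02 1.74895e-01 8.93939e-01 1.06093e+02
8.83723e+00 8.76632e+01 1.74539e-01 8.40063e-01 8.86778e+01
9.42212e+00 7.30511e+01 1.74162e-01 7.87916e-01 7.40131e+01
1.00457e+01 6.08232e+01 1.73762e-01 7.37326e-01 6.17343e+01
1.07106e+01 5.06041e+01 1.73338e-01 6.88200e-01 5.14657e+01
1.14195e+01 4.20703e+01 1.72889e-01 6.40516e-01 4.28837e+01
1.21753e+01 3.49491e+01 1.72414e-01 5.94322e-01 3.57158e+01
1.29811e+01 2.90113e+01 1.71911e-01 5.49717e-01 2.97329e+01
1.38403e+01 2.40640e+01 1.71379e-01 5.06842e-01 2.47422e+01
1.47563e+01 1.99273e+01 1.70817e-01 4.65859e-01 2.05639e+01
1.57330e+01 1.64916e+01 1.70223e-01 4.26933e-01 1.70888e+01
1.67743e+01 1.36406e+01 1.69596e-01 3.90213e-01 1.42004e+01
1.78845e+01 1.12761e+01 1.68933e-01 3.55819e-01 1.18008e+01
1.90682e+01 9.31614e+00 1.68235e-01 3.23823e-01 9.80820e+00
2.03302e+01 7.69246e+00 1.67498e-01 2.94252e-01 8.15421e+00
2.16758e+01 6.34813e+00 1.66723e-01 2.67078e-01 6.78193e+00
2.31104e+01 5.23573e+00 1.65906e-01 2.42230e-01 5.64387e+00
2.46400e+01 4.31578e+00 1.65047e-01 2.19604e-01 4.70043e+00
2.62708e+01 3.55542e+00 1.64145e-01 1.98608e-01 3.91817e+00
2.80096e+01 2.92728e+00 1.63197e-01 1.78855e-01 3.26933e+00
2.98634e+01 2.40870e+00 1.62202e-01 1.60637e-01 2.73154e+00
3.18400e+01 1.98085e+00 1.61160e-01 1.44022e-01 2.28603e+00
3.39473e+01 1.62805e+00 1.60068e-01 1.28963e-01 1.91708e+00
3.61941e+01 1.33731e+00 1.58925e-01 1.15362e-01 1.61159e+00
3.85897e+01 1.09784e+00 1.57732e-01 1.03102e-01 1.35868e+00
4.11437e+01 9.00735e-01 1.56485e-01 9.20647e-02 1.14928e+00
4.38669e+01 7.38583e-01 1.55186e-01 8.21371e-02 9.75906e-01
4.67702e+01 6.05266e-01 1.53833e-01 7.32153e-02 8.32314e-01
4.98657e+01 4.95723e-01 1.52425e-01 6.52045e-02 7.13352e-01
5.31661e+01 4.05767e-01 1.50962e-01 5.80187e-02 6.14748e-01
5.66850e+01 3.31939e-01 1.49445e-01 5.15797e-02 5.32964e-01
6.04367e+01 2.71384e-01 1.47873e-01 4.58162e-02 4.65073e-01
6.44367e+01 2.21745e-01 1.46247e-01 4.06634e-02 4.08655e-01
6.87015e+01 1.81078e-01 1.44566e-01 3.60619e-02 3.61707e-01
7.32486e+01 1.47782e-01 1.42833e-01 3.19575e-02 3.22573e-01
7.80966e+01 1.20538e-01 1.41049e-01 2.83007e-02 2.89887e-01
8.32654e+01 9.82572e-02 1.39214e-01 2.50462e-02 2.62517e-01
8.87764e+01 8.00477e-02 1.37330e-01 2.21528e-02 2.39530e-01
9.46521e+01 6.51742e-02 1.35399e-01 1.95829e-02 2.20156e-01
1.00917e+02 5.30328e-02 1.33423e-01 1.73024e-02 2.03758e-01
1.07596e+02 4.31277e-02 1.31405e-01 1.52806e-02 1.89813e-01
1.14717e+02 3.50517e-02 1.29347e-01 1.34894e-02 1.77888e-01
1.22310e+02 2.84710e-02 1.27252e-01 1.19037e-02 1.67627e-01
1.30405e+02 2.31121e-02 1.25124e-01 1.05008e-02 1.58737e-01
1.39036e+02 1.87507e-02 1.22965e-01 9.26045e-03 1.50976e-01
1.48238e+02 1.52032e-02 1.20778e-01 8.16436e-03 1.44145e-01
1.58049e+02 1.23196e-02 1.18567e-01 7.19623e-03 1.38083e-01
1.68510e+02 9.97692e-03 1.16336e-01 6.34151e-03 1.32655e-01
1.79663e+02 8.07492e-03 1.14088e-01 5.58721e-03 1.27750e-01
1.91554e+02 6.53162e-03 1.11827e-01 4.92176e-03 1.23280e-01
2.04232e+02 5.28012e-03 1.09556e-01 4.33490e-03 1.19171e-01
2.17749e+02 4.26587e-03 1.07278e-01 3.81747e-03 1.15362e-01
2.32161e+02 3.44439e-03 1.04998e-01 3.36139e-03 1.11804e-01
2.47527e+02 2.77944e-03 1.02718e-01 2.95948e-03 1.08456e-01
2.63910e+02 2.24152e-03 1.00441e-01 2.60536e-03 1.05288e-01
2.81377e+02 1.80663e-03 9.81700e-02 2.29342e-03 1.02270e-01
3.00000e+02 1.45524e-03 9.59085e-02 2.01867e-03 9.93824e-02
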