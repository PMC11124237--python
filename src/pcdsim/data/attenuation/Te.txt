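# mass attenuation coefficients for Te (Z=52, A=127.6000)
# photoelectric: Cromer-Liberman f'' (gemmi 0.7.4); incoherent: Klein-Nishina free-electron; coherent: Thomson x IT92 form factor
# K-edge: 31.814 keV
# columns: energy_keV photoelectric incoherent coherent total  [cm^2/g]
1.00000e+00 8.15477e+03 1.62626e-01 8.05056e+00 8.16299e+03
1.06619e+00 7.42441e+03 1.62585e-01 7.99713e+00 7.43257e+03
1.13675e+00 6.45877e+03 1.62540e-01 7.93806e+00 6.46687e+03
1.21199e+00 5.61013e+03 1.62493e-01 7.87296e+00 5.61817e+03
1.29220e+00 4.86556e+03 1.62442e-01 7.80146e+00 4.87353e+03
1.37773e+00 4.21272e+03 1.62388e-01 7.72322e+00 4.22060e+03
1.46892e+00 3.63916e+03 1.62331e-01 7.63794e+00 3.64696e+03
1.56614e+00 3.13746e+03 1.62269e-01 7.54540e+00 3.14517e+03
1.66979e+00 2.70133e+03 1.62204e-01 7.44541e+00 2.70893e+03
1.78031e+00 2.32279e+03 1.62135e-01 7.33789e+00 2.33029e+03
1.89814e+00 1.99475e+03 1.62061e-01 7.22280e+00 2.00214e+03
2.02377e+00 1.71088e+03 1.61982e-01 7.10022e+00 1.71815e+03
2.15771e+00 1.46546e+03 1.61898e-01 6.97030e+00 1.47259e+03
2.30052e+00 1.25374e+03 1.61809e-01 6.83325e+00 1.26073e+03
2.45279e+00 1.07109e+03 1.61714e-01 6.68936e+00 1.07794e+03
2.61512e+00 9.14165e+02 1.61613e-01 6.53894e+00 9.20865e+02
2.78821e+00 7.79510e+02 1.61506e-01 6.38237e+00 7.86054e+02
2.97275e+00 6.64067e+02 1.61391e-01 6.22002e+00 6.70448e+02
3.16950e+00 5.64736e+02 1.61269e-01 6.05227e+00 5.70949e+02
3.37928e+00 4.79789e+02 1.61139e-01 5.87951e+00 4.85829e+02
3.60294e+00 4.07195e+02 1.61001e-01 5.70211e+00 4.13059e+02
3.84140e+00 3.45347e+02 1.60855e-01 5.52043e+00 3.51028e+02
4.09564e+00 2.92744e+02 1.60699e-01 5.33482e+00 2.98239e+02
4.36672e+00 8.19776e+02 1.60533e-01 5.14565e+00 8.25082e+02
4.65573e+00 9.39197e+02 1.60356e-01 4.95330e+00 9.44311e+02
4.96387e+00 9.07889e+02 1.60169e-01 4.75818e+00 9.12807e+02
5.29241e+00 7.72062e+02 1.59969e-01 4.56082e+00 7.76782e+02
5.64269e+00 6.56095e+02 1.59757e-01 4.36183e+00 6.60616e+02
6.01616e+00 5.56656e+02 1.59532e-01 4.16199e+00 5.60978e+02
6.41434e+00 4.71679e+02 1.59293e-01 3.96223e+00 4.75800e+02
6.83888e+00 3.99206e+02 1.59039e-01 3.76362e+00 4.03129e+02
7.29151e+00 3.37553e+02 1.58770e-01 3.56734e+00 3.41279e+02
7.77410e+00 2.85158e+02 1.58484e-01 3.37459e+00 2.88691e+02
8.28864e+00 2.40676e+02 1.58180e-01 3.18651e+00 2.44021e+02
8.83723e+00 2.02950e+02 1.57858e-01 3.00413e+00 2.06112e+02
9.42212e+00 1.70890e+02 1.57517e-01 2.82824e+00 1.73876e+02
1.00457e+01 1.43770e+02 1.57155e-01 2.65941e+00 1.46587e+02
1.07106e+01 1.20870e+02 1.56772e-01 2.49789e+00 1.23525e+02
1.14195e+01 1.01566e+02 1.56366e-01 2.34366e+00 1.04066e+02
1.21753e+01 8.53028e+01 1.55937e-01 2.19647e+00 8.76552e+01
1.29811e+01 7.16099e+01 1.55482e-01 2.05589e+00 7.38212e+01
1.38403e+01 6.00863e+01 1.55001e-01 1.92142e+00 6.21627e+01
1.47563e+01 5.03931e+01 1.54492e-01 1.79253e+00 5.23402e+01
1.57330e+01 4.22425e+01 1.53955e-01 1.66880e+00 4.40653e+01
1.67743e+01 3.53914e+01 1.53387e-01 1.54994e+00 3.70947e+01
1.78845e+01 2.96369e+01 1.52788e-01 1.43580e+00 3.12255e+01
1.90682e+01 2.48059e+01 1.52157e-01 1.32641e+00 2.62845e+01
2.03302e+01 2.07501e+01 1.51491e-01 1.22191e+00 2.21235e+01
2.16758e+01 1.73488e+01 1.50789e-01 1.12251e+00 1.86221e+01
2.31104e+01 1.44989e+01 1.50051e-01 1.02846e+00 1.56774e+01
2.46400e+01 1.21137e+01 1.49274e-01 9.40013e-01 1.32030e+01
2.62708e+01 1.01179e+01 1.48457e-01 8.55161e-01 1.11216e+01
2.80096e+01 8.43466e+00 1.47600e-01 7.73392e-01 9.35565e+00
2.98634e+01 7.02715e+00 1.46701e-01 6.97149e-01 7.87100e+00
3.17822e+01 5.88464e+00 1.45785e-01 6.29155e-01 6.65958e+00
3.18400e+01 3.65486e+01 1.45758e-01 6.27263e-01 3.73216e+01
3.18458e+01 3.65309e+01 1.45755e-01 6.27072e-01 3.73037e+01
3.39473e+01 3.08830e+01 1.44770e-01 5.63748e-01 3.15915e+01
3.61941e+01 2.60873e+01 1.43737e-01 5.06249e-01 2.67372e+01
3.85897e+01 2.20151e+01 1.42657e-01 4.54276e-01 2.26120e+01
4.11437e+01 1.85605e+01 1.41530e-01 4.07323e-01 1.91094e+01
4.38669e+01 1.56292e+01 1.40355e-01 3.64910e-01 1.61344e+01
4.67702e+01 1.31485e+01 1.39131e-01 3.26608e-01 1.36143e+01
4.98657e+01 1.10515e+01 1.37858e-01 2.92031e-01 1.14814e+01
5.31661e+01 9.28035e+00 1.36535e-01 2.60841e-01 9.67772e+00
5.66850e+01 7.78581e+00 1.35163e-01 2.32731e-01 8.15370e+00
6.04367e+01 6.52584e+00 1.33741e-01 2.07428e-01 6.86701e+00
6.44367e+01 5.46406e+00 1.32270e-01 1.84680e-01 5.78101e+00
6.87015e+01 4.56963e+00 1.30750e-01 1.64260e-01 4.86464e+00
7.32486e+01 3.81914e+00 1.29183e-01 1.45955e-01 4.09428e+00
7.80966e+01 3.18983e+00 1.27569e-01 1.29571e-01 3.44697e+00
8.32654e+01 2.65852e+00 1.25909e-01 1.14927e-01 2.89935e+00
8.87764e+01 2.21334e+00 1.24205e-01 1.01855e-01 2.43941e+00
9.46521e+01 1.84261e+00 1.22459e-01 9.02041e-02 2.05527e+00
1.00917e+02 1.53387e+00 1.20672e-01 7.98311e-02 1.73438e+00
1.07596e+02 1.27679e+00 1.18847e-01 7.06070e-02 1.46624e+00
1.14717e+02 1.06272e+00 1.16985e-01 6.24133e-02 1.24212e+00
1.22310e+02 8.84483e-01 1.15091e-01 5.51420e-02 1.05472e+00
1.30405e+02 7.36090e-01 1.13166e-01 4.86952e-02 8.97951e-01
1.39036e+02 6.12551e-01 1.11213e-01 4.29840e-02 7.66747e-01
1.48238e+02 5.09709e-01 1.09235e-01 3.79284e-02 6.56872e-01
1.58049e+02 4.24103e-01 1.07236e-01 3.34560e-02 5.64795e-01
1.68510e+02 3.52850e-01 1.05218e-01 2.95021e-02 4.87570e-01
1.79663e+02 2.93546e-01 1.03185e-01 2.60083e-02 4.22740e-01
1.91554e+02 2.44193e-01 1.01140e-01 2.29228e-02 3.68255e-01
2.04232e+02 2.03123e-01 9.90856e-02 2.01990e-02 3.22407e-01
2.17749e+02 1.68948e-01 9.70257e-02 1.77953e-02 2.83769e-01
2.32161e+02 1.40514e-01 9.49632e-02 1.56751e-02 2.51152e-01
2.47527e+02 1.16857e-01 9.29009e-02 1.38053e-02 2.23563e-01
2.63910e+02 9.71768e-02 9.08416e-02 1.21570e-02 2.00175e-01
2.81377e+02 8.08059e-02 8.87880e-02 1.07041e-02 1.80298e-01
3.00000e+02 6.71888e-02 8.67425e-02 9.42394e-03 1.63355e-01
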