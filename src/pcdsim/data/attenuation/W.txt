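# mass attenuation coefficients for W (Z=74, A=183.8400)
# photoelectric: Cromer-Liberman f'' (gemmi 0.7.4); incoherent: Klein-Nishina free-electron; coherent: Thomson x IT92 form factor
# K-edge: 69.525 keV
# columns: energy_keV photoelectric incoherent coherent total  [cm^2/g]
1.00000e+00 3.51450e+03 1.60631e-01 1.14508e+01 3.52611e+03
1.06619e+00 3.09482e+03 1.60590e-01 1.13933e+01 3.10637e+03
1.13675e+00 2.72144e+03 1.60546e-01 1.13296e+01 2.73293e+03
1.21199e+00 2.39169e+03 1.60499e-01 1.12592e+01 2.40311e+03
1.29220e+00 2.10046e+03 1.60449e-01 1.11816e+01 2.11180e+03
1.37773e+00 1.84327e+03 1.60396e-01 1.10964e+01 1.85452e+03
1.46892e+00 1.61616e+03 1.60339e-01 1.10033e+01 1.62733e+03
1.56614e+00 1.41569e+03 1.60279e-01 1.09017e+01 1.42675e+03
1.66979e+00 1.23878e+03 1.60214e-01 1.07915e+01 1.24973e+03
1.78031e+00 1.08256e+03 1.60146e-01 1.06724e+01 1.09340e+03
1.89814e+00 8.98069e+03 1.60073e-01 1.05442e+01 8.99139e+03
2.02377e+00 3.74085e+03 1.59995e-01 1.04068e+01 3.75142e+03
2.15771e+00 3.19843e+03 1.59912e-01 1.02602e+01 3.20885e+03
2.30052e+00 3.19810e+03 1.59824e-01 1.01043e+01 3.20837e+03
2.45279e+00 2.71628e+03 1.59730e-01 9.93916e+00 2.72638e+03
2.61512e+00 2.48448e+03 1.59630e-01 9.76481e+00 2.49441e+03
2.78821e+00 2.12485e+03 1.59524e-01 9.58125e+00 2.13459e+03
2.97275e+00 1.90804e+03 1.59411e-01 9.38843e+00 1.91759e+03
3.16950e+00 1.63845e+03 1.59291e-01 9.18628e+00 1.64780e+03
3.37928e+00 1.40503e+03 1.59163e-01 8.97472e+00 1.41416e+03
3.60294e+00 1.20333e+03 1.59026e-01 8.75370e+00 1.21224e+03
3.84140e+00 1.02885e+03 1.58881e-01 8.52323e+00 1.03753e+03
4.09564e+00 8.78667e+02 1.58727e-01 8.28346e+00 8.87109e+02
4.36672e+00 7.49836e+02 1.58563e-01 8.03473e+00 7.58029e+02
4.65573e+00 6.39318e+02 1.58389e-01 7.77759e+00 6.47254e+02
4.96387e+00 5.44506e+02 1.58204e-01 7.51286e+00 5.52177e+02
5.29241e+00 4.63352e+02 1.58007e-01 7.24153e+00 4.70752e+02
5.64269e+00 3.93967e+02 1.57797e-01 6.96481e+00 4.01089e+02
6.01616e+00 3.34723e+02 1.57575e-01 6.68397e+00 3.41565e+02
6.41434e+00 2.84221e+02 1.57339e-01 6.40035e+00 2.90779e+02
6.83888e+00 2.41198e+02 1.57088e-01 6.11521e+00 2.47470e+02
7.29151e+00 2.04567e+02 1.56822e-01 5.82973e+00 2.10554e+02
7.77410e+00 1.73398e+02 1.56539e-01 5.54496e+00 1.79100e+02
8.28864e+00 1.46889e+02 1.56240e-01 5.26185e+00 1.52307e+02
8.83723e+00 1.24363e+02 1.55922e-01 4.98124e+00 1.29500e+02
9.42212e+00 1.05153e+02 1.55585e-01 4.70398e+00 1.10012e+02
1.00457e+01 8.88614e+01 1.55227e-01 4.43094e+00 9.34475e+01
1.07106e+01 2.01643e+02 1.54849e-01 4.16310e+00 2.05961e+02
1.14195e+01 1.69396e+02 1.54448e-01 3.90155e+00 1.73452e+02
1.21753e+01 2.29302e+02 1.54023e-01 3.64746e+00 2.33104e+02
1.29811e+01 1.94791e+02 1.53574e-01 3.40203e+00 1.98347e+02
1.38403e+01 1.65162e+02 1.53099e-01 3.16640e+00 1.68482e+02
1.47563e+01 1.39927e+02 1.52597e-01 2.94153e+00 1.43021e+02
1.57330e+01 1.18430e+02 1.52066e-01 2.72819e+00 1.21311e+02
1.67743e+01 1.00151e+02 1.51506e-01 2.52682e+00 1.02830e+02
1.78845e+01 8.46346e+01 1.50914e-01 2.33759e+00 8.71231e+01
1.90682e+01 7.14719e+01 1.50290e-01 2.16038e+00 7.37826e+01
2.03302e+01 6.03142e+01 1.49632e-01 1.99486e+00 6.24587e+01
2.16758e+01 5.08578e+01 1.48939e-01 1.84052e+00 5.28473e+01
2.31104e+01 4.28563e+01 1.48210e-01 1.69678e+00 4.47013e+01
2.46400e+01 3.60882e+01 1.47443e-01 1.56304e+00 3.77987e+01
2.62708e+01 3.03720e+01 1.46636e-01 1.43146e+00 3.19501e+01
2.80096e+01 2.55306e+01 1.45789e-01 1.29867e+00 2.69751e+01
2.98634e+01 2.14483e+01 1.44901e-01 1.17209e+00 2.27653e+01
3.18400e+01 1.80125e+01 1.43969e-01 1.05491e+00 1.92113e+01
3.39473e+01 1.51217e+01 1.42994e-01 9.48013e-01 1.62127e+01
3.61941e+01 1.26903e+01 1.41974e-01 8.51194e-01 1.36835e+01
3.85897e+01 1.06459e+01 1.40907e-01 7.63768e-01 1.15506e+01
4.11437e+01 8.92749e+00 1.39794e-01 6.84901e-01 9.75218e+00
4.38669e+01 7.48355e+00 1.38633e-01 6.13762e-01 8.23594e+00
4.67702e+01 6.26898e+00 1.37424e-01 5.49585e-01 6.95599e+00
4.98657e+01 5.24961e+00 1.36166e-01 4.91688e-01 5.87746e+00
5.31661e+01 4.39297e+00 1.34860e-01 4.39471e-01 4.96731e+00
5.66850e+01 3.67365e+00 1.33504e-01 3.92403e-01 4.19956e+00
6.04367e+01 3.07169e+00 1.32100e-01 3.50014e-01 3.55380e+00
6.44367e+01 2.56798e+00 1.30647e-01 3.11878e-01 3.01051e+00
6.87015e+01 2.14655e+00 1.29146e-01 2.77613e-01 2.55330e+00
6.94555e+01 2.08197e+00 1.28886e-01 2.72137e-01 2.48299e+00
6.95945e+01 1.06539e+01 1.28838e-01 2.71145e-01 1.10539e+01
7.32486e+01 9.36172e+00 1.27598e-01 2.46866e-01 9.73618e+00
7.80966e+01 7.91233e+00 1.26004e-01 2.19316e-01 8.25765e+00
8.32654e+01 6.68915e+00 1.24364e-01 1.94665e-01 7.00818e+00
8.87764e+01 5.65222e+00 1.22681e-01 1.72638e-01 5.94754e+00
9.46521e+01 4.76692e+00 1.20956e-01 1.52984e-01 5.04086e+00
1.00917e+02 4.01686e+00 1.19191e-01 1.35468e-01 4.27152e+00
1.07596e+02 3.38355e+00 1.17389e-01 1.19878e-01 3.62082e+00
1.14717e+02 2.84901e+00 1.15550e-01 1.06017e-01 3.07058e+00
1.22310e+02 2.39801e+00 1.13679e-01 9.37066e-02 2.60540e+00
1.30405e+02 2.01763e+00 1.11777e-01 8.27836e-02 2.21219e+00
1.39036e+02 1.69692e+00 1.09848e-01 7.31005e-02 1.87987e+00
1.48238e+02 1.42074e+00 1.07895e-01 6.45234e-02 1.59316e+00
1.58049e+02 1.18991e+00 1.05920e-01 5.69315e-02 1.35276e+00
1.68510e+02 9.96930e-01 1.03927e-01 5.02162e-02 1.15107e+00
1.79663e+02 8.35533e-01 1.01919e-01 4.42797e-02 9.81732e-01
1.91554e+02 7.00507e-01 9.98989e-02 3.90346e-02 8.39441e-01
2.04232e+02 5.87505e-01 9.78700e-02 3.44027e-02 7.19777e-01
2.17749e+02 4.92902e-01 9.58354e-02 3.03138e-02 6.19051e-01
2.32161e+02 4.13676e-01 9.37982e-02 2.67060e-02 5.34180e-01
2.47527e+02 3.47306e-01 9.17612e-02 2.35235e-02 4.62591e-01
2.63910e+02 2.91686e-01 8.97271e-02 2.07172e-02 4.02131e-01
2.81377e+02 2.45061e-01 8.76987e-02 1.82433e-02 3.51003e-01
3.00000e+02 2.05962e-01 8.56784e-02 1.60629e-02 3.07703e-01
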