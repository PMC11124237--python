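# mass attenuation coefficients for La (Z=57, A=138.9050)
# photoelectric: Cromer-Liberman f'' (gemmi 0.7.4); incoherent: Klein-Nishina free-electron; coherent: Thomson x IT92 form factor
# K-edge: 38.925 keV
# columns: energy_keV photoelectric incoherent coherent total  [cm^2/g]
1.00000e+00 8.96659e+03 1.63755e-01 8.73840e+00 8.97549e+03
1.06619e+00 7.74621e+03 1.63713e-01 8.66948e+00 7.75504e+03
1.13675e+00 7.75930e+03 1.63668e-01 8.59479e+00 7.76806e+03
1.21199e+00 7.11881e+03 1.63621e-01 8.51419e+00 7.12749e+03
1.29220e+00 6.15805e+03 1.63570e-01 8.42756e+00 6.16665e+03
1.37773e+00 5.59692e+03 1.63515e-01 8.33482e+00 5.60541e+03
1.46892e+00 4.85639e+03 1.63457e-01 8.23593e+00 4.86479e+03
1.56614e+00 4.20317e+03 1.63396e-01 8.13084e+00 4.21146e+03
1.66979e+00 3.63146e+03 1.63330e-01 8.01950e+00 3.63964e+03
1.78031e+00 3.13312e+03 1.63260e-01 7.90185e+00 3.14119e+03
1.89814e+00 2.69904e+03 1.63186e-01 7.77780e+00 2.70698e+03
2.02377e+00 2.32182e+03 1.63107e-01 7.64721e+00 2.32963e+03
2.15771e+00 1.99472e+03 1.63022e-01 7.50990e+00 2.00239e+03
2.30052e+00 1.71130e+03 1.62932e-01 7.36571e+00 1.71883e+03
2.45279e+00 1.46605e+03 1.62837e-01 7.21446e+00 1.47343e+03
2.61512e+00 1.25439e+03 1.62735e-01 7.05607e+00 1.26161e+03
2.78821e+00 1.07211e+03 1.62627e-01 6.89055e+00 1.07917e+03
2.97275e+00 9.15351e+02 1.62511e-01 6.71805e+00 9.22232e+02
3.16950e+00 7.80182e+02 1.62389e-01 6.53891e+00 7.86884e+02
3.37928e+00 6.64374e+02 1.62258e-01 6.35364e+00 6.70889e+02
3.60294e+00 5.65147e+02 1.62119e-01 6.16293e+00 5.71472e+02
3.84140e+00 4.80429e+02 1.61971e-01 5.96758e+00 4.86558e+02
4.09564e+00 4.08155e+02 1.61814e-01 5.76847e+00 4.14086e+02
4.36672e+00 3.46546e+02 1.61647e-01 5.56650e+00 3.52274e+02
4.65573e+00 2.94057e+02 1.61469e-01 5.36253e+00 2.99581e+02
4.96387e+00 2.49334e+02 1.61280e-01 5.15732e+00 2.54653e+02
5.29241e+00 2.11221e+02 1.61080e-01 4.95150e+00 2.16334e+02
5.64269e+00 5.38807e+02 1.60866e-01 4.74558e+00 5.43713e+02
6.01616e+00 6.24559e+02 1.60640e-01 4.53994e+00 6.29260e+02
6.41434e+00 6.09213e+02 1.60399e-01 4.33489e+00 6.13708e+02
6.83888e+00 5.17683e+02 1.60143e-01 4.13075e+00 5.21974e+02
7.29151e+00 4.39134e+02 1.59872e-01 3.92791e+00 4.43222e+02
7.77410e+00 3.72067e+02 1.59584e-01 3.72688e+00 3.75954e+02
8.28864e+00 3.14922e+02 1.59278e-01 3.52834e+00 3.18610e+02
8.83723e+00 2.66318e+02 1.58954e-01 3.33311e+00 2.69810e+02
9.42212e+00 2.24887e+02 1.58611e-01 3.14211e+00 2.28188e+02
1.00457e+01 1.89760e+02 1.58246e-01 2.95629e+00 1.92875e+02
1.07106e+01 1.60014e+02 1.57860e-01 2.77654e+00 1.62948e+02
1.14195e+01 1.34813e+02 1.57452e-01 2.60364e+00 1.37574e+02
1.21753e+01 1.13480e+02 1.57019e-01 2.43815e+00 1.16075e+02
1.29811e+01 9.54437e+01 1.56561e-01 2.28040e+00 9.78807e+01
1.38403e+01 8.02253e+01 1.56077e-01 2.13046e+00 8.25119e+01
1.47563e+01 6.74011e+01 1.55565e-01 1.98816e+00 6.95449e+01
1.57330e+01 5.65998e+01 1.55024e-01 1.85316e+00 5.86080e+01
1.67743e+01 4.75062e+01 1.54452e-01 1.72495e+00 4.93856e+01
1.78845e+01 3.98546e+01 1.53849e-01 1.60299e+00 4.16115e+01
1.90682e+01 3.34195e+01 1.53213e-01 1.48676e+00 3.50595e+01
2.03302e+01 2.80099e+01 1.52542e-01 1.37583e+00 2.95383e+01
2.16758e+01 2.34646e+01 1.51836e-01 1.26989e+00 2.48863e+01
2.31104e+01 1.96472e+01 1.51092e-01 1.16878e+00 2.09671e+01
2.46400e+01 1.64423e+01 1.50310e-01 1.07250e+00 1.76651e+01
2.62708e+01 1.37536e+01 1.49488e-01 9.78296e-01 1.48814e+01
2.80096e+01 1.14868e+01 1.48625e-01 8.85978e-01 1.25214e+01
2.98634e+01 9.58575e+00 1.47719e-01 7.99249e-01 1.05327e+01
3.18400e+01 7.99848e+00 1.46769e-01 7.19510e-01 8.86476e+00
3.39473e+01 6.67325e+00 1.45775e-01 6.46974e-01 7.46600e+00
3.61941e+01 5.56683e+00 1.44735e-01 5.81309e-01 6.29287e+00
3.85897e+01 4.64314e+00 1.43648e-01 5.21970e-01 5.30876e+00
3.88861e+01 4.54359e+00 1.43515e-01 5.15279e-01 5.20238e+00
3.89639e+01 2.68781e+01 1.43480e-01 5.13544e-01 2.75351e+01
4.11437e+01 2.33329e+01 1.42513e-01 4.68368e-01 2.39438e+01
4.38669e+01 1.97164e+01 1.41329e-01 4.19944e-01 2.02777e+01
4.67702e+01 1.66446e+01 1.40097e-01 3.76194e-01 1.71609e+01
4.98657e+01 1.40380e+01 1.38815e-01 3.36671e-01 1.45135e+01
5.31661e+01 1.18263e+01 1.37483e-01 3.00986e-01 1.22648e+01
5.66850e+01 9.95354e+00 1.36101e-01 2.68790e-01 1.03584e+01
6.04367e+01 8.36962e+00 1.34669e-01 2.39774e-01 8.74407e+00
6.44367e+01 7.03124e+00 1.33188e-01 2.13657e-01 7.37808e+00
6.87015e+01 5.90137e+00 1.31658e-01 1.90182e-01 6.22321e+00
7.32486e+01 4.94841e+00 1.30080e-01 1.69112e-01 5.24761e+00
7.80966e+01 4.14542e+00 1.28454e-01 1.50231e-01 4.42410e+00
8.32654e+01 3.46218e+00 1.26783e-01 1.33335e-01 3.72230e+00
8.87764e+01 2.88742e+00 1.25067e-01 1.18239e-01 3.13072e+00
9.46521e+01 2.40810e+00 1.23309e-01 1.04768e-01 2.63617e+00
1.00917e+02 2.00837e+00 1.21509e-01 9.27651e-02 2.22264e+00
1.07596e+02 1.67500e+00 1.19672e-01 8.20821e-02 1.87676e+00
1.14717e+02 1.39698e+00 1.17798e-01 7.25852e-02 1.58736e+00
1.22310e+02 1.16511e+00 1.15890e-01 6.41516e-02 1.34516e+00
1.30405e+02 9.71735e-01 1.13951e-01 5.66694e-02 1.14236e+00
1.39036e+02 8.10454e-01 1.11985e-01 5.00372e-02 9.72476e-01
1.48238e+02 6.75943e-01 1.09993e-01 4.41633e-02 8.30100e-01
1.58049e+02 5.63758e-01 1.07980e-01 3.89646e-02 7.10702e-01
1.68510e+02 4.70192e-01 1.05948e-01 3.43666e-02 6.10507e-01
1.79663e+02 3.92156e-01 1.03901e-01 3.03023e-02 5.26359e-01
1.91554e+02 3.27072e-01 1.01842e-01 2.67116e-02 4.55625e-01
2.04232e+02 2.72790e-01 9.97734e-02 2.35409e-02 3.96104e-01
2.17749e+02 2.27517e-01 9.76993e-02 2.07423e-02 3.45959e-01
2.32161e+02 1.89759e-01 9.56224e-02 1.82729e-02 3.03654e-01
2.47527e+02 1.58268e-01 9.35458e-02 1.60949e-02 2.67909e-01
2.63910e+02 1.32004e-01 9.14722e-02 1.41745e-02 2.37651e-01
2.81377e+02 1.10099e-01 8.94043e-02 1.24815e-02 2.11985e-01
3.00000e+02 9.18305e-02 8.73447e-02 1.09895e-02 1.90165e-01
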