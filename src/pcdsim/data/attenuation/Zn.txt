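# mass attenuation coefficients for Zn (Z=30, A=65.3800)
# photoelectric: Cromer-Liberman f'' (gemmi 0.7.4); incoherent: Klein-Nishina free-electron; coherent: Thomson x IT92 form factor
# K-edge: 9.659 keV
# columns: energy_keV photoelectric incoherent coherent total  [cm^2/g]
1.00000e+00 1.45528e+03 1.83111e-01 5.24659e+00 1.46071e+03
1.06619e+00 1.34544e+04 1.83064e-01 5.21434e+00 1.34598e+04
1.13675e+00 8.40445e+03 1.83014e-01 5.17862e+00 8.40982e+03
1.21199e+00 8.02639e+03 1.82960e-01 5.13918e+00 8.03172e+03
1.29220e+00 6.81864e+03 1.82903e-01 5.09576e+00 6.82392e+03
1.37773e+00 5.82613e+03 1.82843e-01 5.04814e+00 5.83136e+03
1.46892e+00 4.99315e+03 1.82778e-01 4.99609e+00 4.99833e+03
1.56614e+00 4.27218e+03 1.82709e-01 4.93943e+00 4.27730e+03
1.66979e+00 3.64727e+03 1.82636e-01 4.87799e+00 3.65233e+03
1.78031e+00 3.10920e+03 1.82558e-01 4.81166e+00 3.11419e+03
1.89814e+00 2.64695e+03 1.82474e-01 4.74034e+00 2.65188e+03
2.02377e+00 2.25045e+03 1.82386e-01 4.66398e+00 2.25530e+03
2.15771e+00 1.90988e+03 1.82291e-01 4.58256e+00 1.91464e+03
2.30052e+00 1.61889e+03 1.82191e-01 4.49606e+00 1.62356e+03
2.45279e+00 1.37078e+03 1.82084e-01 4.40451e+00 1.37537e+03
2.61512e+00 1.15952e+03 1.81970e-01 4.30791e+00 1.16401e+03
2.78821e+00 9.79920e+02 1.81849e-01 4.20626e+00 9.84308e+02
2.97275e+00 8.27402e+02 1.81720e-01 4.09955e+00 8.31683e+02
3.16950e+00 6.97524e+02 1.81583e-01 3.98777e+00 7.01693e+02
3.37928e+00 5.87576e+02 1.81437e-01 3.87091e+00 5.91628e+02
3.60294e+00 4.94644e+02 1.81281e-01 3.74900e+00 4.98575e+02
3.84140e+00 4.16148e+02 1.81116e-01 3.62214e+00 4.19951e+02
4.09564e+00 3.49894e+02 1.80940e-01 3.49051e+00 3.53565e+02
4.36672e+00 2.94011e+02 1.80754e-01 3.35445e+00 2.97546e+02
4.65573e+00 2.46805e+02 1.80555e-01 3.21441e+00 2.50200e+02
4.96387e+00 2.07043e+02 1.80344e-01 3.07104e+00 2.10294e+02
5.29241e+00 1.73585e+02 1.80119e-01 2.92509e+00 1.76691e+02
5.64269e+00 1.45441e+02 1.79881e-01 2.77747e+00 1.48398e+02
6.01616e+00 1.21813e+02 1.79627e-01 2.62915e+00 1.24621e+02
6.41434e+00 1.01984e+02 1.79358e-01 2.48116e+00 1.04644e+02
6.83888e+00 8.53498e+01 1.79072e-01 2.33452e+00 8.78634e+01
7.29151e+00 7.14010e+01 1.78769e-01 2.19023e+00 7.37700e+01
7.77410e+00 5.97084e+01 1.78447e-01 2.04924e+00 6.19361e+01
8.28864e+00 4.99106e+01 1.78105e-01 1.91241e+00 5.20011e+01
8.83723e+00 4.17035e+01 1.77743e-01 1.78052e+00 4.36618e+01
9.42212e+00 3.47776e+01 1.77358e-01 1.65420e+00 3.66091e+01
9.64934e+00 3.25027e+01 1.77210e-01 1.60877e+00 3.42887e+01
9.66866e+00 2.58877e+02 1.77197e-01 1.60500e+00 2.60660e+02
1.00457e+01 2.30731e+02 1.76951e-01 1.53400e+00 2.32441e+02
1.07106e+01 1.94994e+02 1.76520e-01 1.42029e+00 1.96590e+02
1.14195e+01 1.65101e+02 1.76062e-01 1.31333e+00 1.66590e+02
1.21753e+01 1.39596e+02 1.75579e-01 1.21319e+00 1.40985e+02
1.29811e+01 1.17796e+02 1.75067e-01 1.11981e+00 1.19091e+02
1.38403e+01 9.92325e+01 1.74525e-01 1.03299e+00 1.00440e+02
1.47563e+01 8.35067e+01 1.73952e-01 9.52394e-01 8.46330e+01
1.57330e+01 7.01986e+01 1.73347e-01 8.77612e-01 7.12496e+01
1.67743e+01 5.89486e+01 1.72708e-01 8.08178e-01 5.99295e+01
1.78845e+01 4.94487e+01 1.72034e-01 7.43619e-01 5.03643e+01
1.90682e+01 4.14352e+01 1.71323e-01 6.83483e-01 4.22900e+01
2.03302e+01 3.46695e+01 1.70573e-01 6.27371e-01 3.54675e+01
2.16758e+01 2.89802e+01 1.69783e-01 5.74949e-01 2.97250e+01
2.31104e+01 2.42035e+01 1.68951e-01 5.25951e-01 2.48985e+01
2.46400e+01 2.01968e+01 1.68077e-01 4.80174e-01 2.08451e+01
2.62708e+01 1.68389e+01 1.67157e-01 4.36159e-01 1.74422e+01
2.80096e+01 1.40220e+01 1.66192e-01 3.93515e-01 1.45817e+01
2.98634e+01 1.16665e+01 1.65179e-01 3.53724e-01 1.21854e+01
3.18400e+01 9.69998e+00 1.64117e-01 3.17324e-01 1.01814e+01
3.39473e+01 8.05930e+00 1.63006e-01 2.84360e-01 8.50666e+00
3.61941e+01 6.69142e+00 1.61842e-01 2.54650e-01 7.10791e+00
3.85897e+01 5.55179e+00 1.60627e-01 2.27924e-01 5.94034e+00
4.11437e+01 4.60299e+00 1.59358e-01 2.03895e-01 4.96624e+00
4.38669e+01 3.80921e+00 1.58034e-01 1.82290e-01 4.14954e+00
4.67702e+01 3.14966e+00 1.56656e-01 1.62862e-01 3.46918e+00
4.98657e+01 2.60332e+00 1.55222e-01 1.45391e-01 2.90394e+00
5.31661e+01 2.15093e+00 1.53733e-01 1.29685e-01 2.43435e+00
5.66850e+01 1.77647e+00 1.52188e-01 1.15573e-01 2.04423e+00
6.04367e+01 1.46664e+00 1.50587e-01 1.02903e-01 1.72013e+00
6.44367e+01 1.21038e+00 1.48931e-01 9.15390e-02 1.45085e+00
6.87015e+01 9.98500e-01 1.47220e-01 8.13566e-02 1.22708e+00
7.32486e+01 8.23392e-01 1.45455e-01 7.22441e-02 1.04109e+00
7.80966e+01 6.78726e-01 1.43638e-01 6.40991e-02 8.86463e-01
8.32654e+01 5.59258e-01 1.41769e-01 5.68277e-02 7.57854e-01
8.87764e+01 4.60637e-01 1.39850e-01 5.03442e-02 6.50831e-01
9.46521e+01 3.79256e-01 1.37884e-01 4.45698e-02 5.61710e-01
1.00917e+02 3.12130e-01 1.35872e-01 3.94328e-02 4.87434e-01
1.07596e+02 2.56782e-01 1.33817e-01 3.48676e-02 4.25467e-01
1.14717e+02 2.11165e-01 1.31721e-01 3.08146e-02 3.73701e-01
1.22310e+02 1.73583e-01 1.29588e-01 2.72195e-02 3.30390e-01
1.30405e+02 1.42632e-01 1.27420e-01 2.40332e-02 2.94086e-01
1.39036e+02 1.17154e-01 1.25221e-01 2.12115e-02 2.63586e-01
1.48238e+02 9.61878e-02 1.22995e-01 1.87144e-02 2.37897e-01
1.58049e+02 7.89425e-02 1.20743e-01 1.65059e-02 2.16192e-01
1.68510e+02 6.47633e-02 1.18471e-01 1.45539e-02 1.97789e-01
1.79663e+02 5.31097e-02 1.16182e-01 1.28293e-02 1.82121e-01
1.91554e+02 4.35357e-02 1.13879e-01 1.13065e-02 1.68722e-01
2.04232e+02 3.56735e-02 1.11567e-01 9.96239e-03 1.57202e-01
2.17749e+02 2.92195e-02 1.09247e-01 8.77643e-03 1.47243e-01
2.32161e+02 2.39236e-02 1.06925e-01 7.73039e-03 1.38579e-01
2.47527e+02 1.95799e-02 1.04603e-01 6.80802e-03 1.30991e-01
2.63910e+02 1.60185e-02 1.02284e-01 5.99493e-03 1.24298e-01
2.81377e+02 1.30998e-02 9.99719e-02 5.27834e-03 1.18350e-01
3.00000e+02 1.07086e-02 9.76688e-02 4.64693e-03 1.13024e-01
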