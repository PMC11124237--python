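# mass attenuation coefficients for H (Z=1, A=1.0079)
# photoelectric: Cromer-Liberman f'' (gemmi 0.7.4); incoherent: Klein-Nishina free-electron; coherent: Thomson x IT92 form factor
# K-edge: none keV
# columns: energy_keV photoelectric incoherent coherent total  [cm^2/g]
1.00000e+00 0.00000e+00 3.95917e-01 3.58675e-01 7.54592e-01
1.06619e+00 0.00000e+00 3.95815e-01 3.53898e-01 7.49713e-01
1.13675e+00 0.00000e+00 3.95706e-01 3.48605e-01 7.44311e-01
1.21199e+00 0.00000e+00 3.95591e-01 3.42759e-01 7.38349e-01
1.29220e+00 0.00000e+00 3.95467e-01 3.36324e-01 7.31792e-01
1.37773e+00 0.00000e+00 3.95336e-01 3.29271e-01 7.24607e-01
1.46892e+00 0.00000e+00 3.95196e-01 3.21572e-01 7.16769e-01
1.56614e+00 0.00000e+00 3.95047e-01 3.13209e-01 7.08257e-01
1.66979e+00 0.00000e+00 3.94889e-01 3.04173e-01 6.99061e-01
1.78031e+00 0.00000e+00 3.94720e-01 2.94464e-01 6.89184e-01
1.89814e+00 0.00000e+00 3.94540e-01 2.84098e-01 6.78638e-01
2.02377e+00 0.00000e+00 3.94348e-01 2.73106e-01 6.67454e-01
2.15771e+00 0.00000e+00 3.94144e-01 2.61532e-01 6.55677e-01
2.30052e+00 0.00000e+00 3.93927e-01 2.49442e-01 6.43369e-01
2.45279e+00 0.00000e+00 3.93696e-01 2.36914e-01 6.30610e-01
2.61512e+00 0.00000e+00 3.93450e-01 2.24045e-01 6.17494e-01
2.78821e+00 0.00000e+00 3.93188e-01 2.10943e-01 6.04131e-01
2.97275e+00 0.00000e+00 3.92909e-01 1.97728e-01 5.90637e-01
3.16950e+00 0.00000e+00 3.92612e-01 1.84526e-01 5.77138e-01
3.37928e+00 0.00000e+00 3.92297e-01 1.71461e-01 5.63757e-01
3.60294e+00 0.00000e+00 3.91961e-01 1.58656e-01 5.50617e-01
3.84140e+00 0.00000e+00 3.91603e-01 1.46223e-01 5.37827e-01
4.09564e+00 0.00000e+00 3.91223e-01 1.34261e-01 5.25485e-01
4.36672e+00 0.00000e+00 3.90819e-01 1.22852e-01 5.13671e-01
4.65573e+00 0.00000e+00 3.90390e-01 1.12057e-01 5.02447e-01
4.96387e+00 0.00000e+00 3.89933e-01 1.01920e-01 4.91853e-01
5.29241e+00 0.00000e+00 3.89447e-01 9.24649e-02 4.81912e-01
5.64269e+00 0.00000e+00 3.88932e-01 8.36975e-02 4.72629e-01
6.01616e+00 0.00000e+00 3.88384e-01 7.56103e-02 4.63994e-01
6.41434e+00 0.00000e+00 3.87802e-01 6.81834e-02 4.55985e-01
6.83888e+00 0.00000e+00 3.87184e-01 6.13880e-02 4.48572e-01
7.29151e+00 0.00000e+00 3.86528e-01 5.51894e-02 4.41717e-01
7.77410e+00 0.00000e+00 3.85831e-01 4.95491e-02 4.35380e-01
8.28864e+00 0.00000e+00 3.85093e-01 4.44271e-02 4.29520e-01
8.83723e+00 0.00000e+00 3.84309e-01 3.97840e-02 4.24093e-01
9.42212e+00 0.00000e+00 3.83478e-01 3.55818e-02 4.19060e-01
1.00457e+01 0.00000e+00 3.82598e-01 3.17845e-02 4.14382e-01
1.07106e+01 0.00000e+00 3.81664e-01 2.83587e-02 4.10023e-01
1.14195e+01 0.00000e+00 3.80676e-01 2.52731e-02 4.05949e-01
1.21753e+01 0.00000e+00 3.79630e-01 2.24986e-02 4.02129e-01
1.29811e+01 0.00000e+00 3.78523e-01 2.00078e-02 3.98531e-01
1.38403e+01 0.00000e+00 3.77352e-01 1.77754e-02 3.95127e-01
1.47563e+01 0.00000e+00 3.76114e-01 1.57776e-02 3.91891e-01
1.57330e+01 0.00000e+00 3.74806e-01 1.39923e-02 3.88798e-01
1.67743e+01 0.00000e+00 3.73424e-01 1.23992e-02 3.85823e-01
1.78845e+01 0.00000e+00 3.71966e-01 1.09794e-02 3.82945e-01
1.90682e+01 0.00000e+00 3.70428e-01 9.71560e-03 3.80143e-01
2.03302e+01 0.00000e+00 3.68806e-01 8.59200e-03 3.77398e-01
2.16758e+01 0.00000e+00 3.67099e-01 7.59411e-03 3.74693e-01
2.31104e+01 0.00000e+00 3.65301e-01 6.70874e-03 3.72009e-01
2.46400e+01 0.00000e+00 3.63410e-01 5.92391e-03 3.69333e-01
2.62708e+01 0.00000e+00 3.61422e-01 5.22869e-03 3.66651e-01
2.80096e+01 0.00000e+00 3.59335e-01 4.61324e-03 3.63948e-01
2.98634e+01 0.00000e+00 3.57145e-01 4.06884e-03 3.61214e-01
3.18400e+01 0.00000e+00 3.54849e-01 3.58760e-03 3.58437e-01
3.39473e+01 0.00000e+00 3.52445e-01 3.16244e-03 3.55608e-01
3.61941e+01 0.00000e+00 3.49930e-01 2.78701e-03 3.52717e-01
3.85897e+01 0.00000e+00 3.47301e-01 2.45564e-03 3.49757e-01
4.11437e+01 0.00000e+00 3.44557e-01 2.16328e-03 3.46721e-01
4.38669e+01 0.00000e+00 3.41696e-01 1.90542e-03 3.43602e-01
4.67702e+01 0.00000e+00 3.38716e-01 1.67805e-03 3.40394e-01
4.98657e+01 0.00000e+00 3.35616e-01 1.47762e-03 3.37094e-01
5.31661e+01 0.00000e+00 3.32396e-01 1.30099e-03 3.33697e-01
5.66850e+01 0.00000e+00 3.29055e-01 1.14536e-03 3.30201e-01
6.04367e+01 0.00000e+00 3.25594e-01 1.00825e-03 3.26602e-01
6.44367e+01 0.00000e+00 3.22013e-01 8.87489e-04 3.22901e-01
6.87015e+01 0.00000e+00 3.18314e-01 7.81136e-04 3.19095e-01
7.32486e+01 0.00000e+00 3.14498e-01 6.87485e-04 3.15185e-01
7.80966e+01 0.00000e+00 3.10568e-01 6.05029e-04 3.11173e-01
8.32654e+01 0.00000e+00 3.06527e-01 5.32436e-04 3.07060e-01
8.87764e+01 0.00000e+00 3.02379e-01 4.68533e-04 3.02848e-01
9.46521e+01 0.00000e+00 2.98128e-01 4.12284e-04 2.98540e-01
1.00917e+02 0.00000e+00 2.93777e-01 3.62776e-04 2.94140e-01
1.07596e+02 0.00000e+00 2.89334e-01 3.19203e-04 2.89653e-01
1.14717e+02 0.00000e+00 2.84803e-01 2.80856e-04 2.85084e-01
1.22310e+02 0.00000e+00 2.80191e-01 2.47110e-04 2.80438e-01
1.30405e+02 0.00000e+00 2.75504e-01 2.17414e-04 2.75721e-01
1.39036e+02 0.00000e+00 2.70750e-01 1.91284e-04 2.70941e-01
1.48238e+02 0.00000e+00 2.65935e-01 1.68290e-04 2.66103e-01
1.58049e+02 0.00000e+00 2.61067e-01 1.48059e-04 2.61215e-01
1.68510e+02 0.00000e+00 2.56155e-01 1.30258e-04 2.56285e-01
1.79663e+02 0.00000e+00 2.51205e-01 1.14596e-04 2.51320e-01
1.91554e+02 0.00000e+00 2.46226e-01 1.00816e-04 2.46327e-01
2.04232e+02 0.00000e+00 2.41225e-01 8.86917e-05 2.41314e-01
2.17749e+02 0.00000e+00 2.36211e-01 7.80250e-05 2.36289e-01
2.32161e+02 0.00000e+00 2.31189e-01 6.86406e-05 2.31258e-01
2.47527e+02 0.00000e+00 2.26169e-01 6.03843e-05 2.26229e-01
2.63910e+02 0.00000e+00 2.21155e-01 5.31207e-05 2.21208e-01
2.81377e+02 0.00000e+00 2.16156e-01 4.67305e-05 2.16203e-01
3.00000e+02 0.00000e+00 2.11176e-01 4.11087e-05 2.11217e-01
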