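# mass attenuation coefficients for Al (Z=13, A=26.9815)
# photoelectric: Cromer-Liberman f'' (gemmi 0.7.4); incoherent: Klein-Nishina free-electron; coherent: Thomson x IT92 form factor
# K-edge: none keV
# columns: energy_keV photoelectric incoherent coherent total  [cm^2/g]
1.00000e+00 1.10031e+03 1.92272e-01 2.25663e+00 1.10276e+03
1.06619e+00 9.28203e+02 1.92222e-01 2.22869e+00 9.30624e+02
1.13675e+00 7.82593e+02 1.92169e-01 2.19840e+00 7.84984e+02
1.21199e+00 6.59463e+02 1.92113e-01 2.16573e+00 6.61820e+02
1.29220e+00 5.55395e+02 1.92053e-01 2.13070e+00 5.57717e+02
1.37773e+00 4.67460e+02 1.91990e-01 2.09335e+00 4.69745e+02
1.46892e+00 3.92939e+02 1.91922e-01 2.05379e+00 3.95184e+02
1.56614e+00 4.05117e+03 1.91849e-01 2.01215e+00 4.05337e+03
1.66979e+00 3.61792e+03 1.91772e-01 1.96862e+00 3.62008e+03
1.78031e+00 3.06305e+03 1.91690e-01 1.92342e+00 3.06517e+03
1.89814e+00 2.59232e+03 1.91603e-01 1.87679e+00 2.59439e+03
2.02377e+00 2.19311e+03 1.91510e-01 1.82899e+00 2.19513e+03
2.15771e+00 1.85940e+03 1.91411e-01 1.78029e+00 1.86137e+03
2.30052e+00 1.57437e+03 1.91305e-01 1.73092e+00 1.57629e+03
2.45279e+00 1.33118e+03 1.91193e-01 1.68108e+00 1.33305e+03
2.61512e+00 1.12399e+03 1.91074e-01 1.63096e+00 1.12581e+03
2.78821e+00 9.47732e+02 1.90946e-01 1.58068e+00 9.49504e+02
2.97275e+00 7.98003e+02 1.90811e-01 1.53029e+00 7.99724e+02
3.16950e+00 6.70698e+02 1.90667e-01 1.47983e+00 6.72369e+02
3.37928e+00 5.62577e+02 1.90514e-01 1.42929e+00 5.64196e+02
3.60294e+00 4.71461e+02 1.90350e-01 1.37862e+00 4.73030e+02
3.84140e+00 3.94746e+02 1.90177e-01 1.32778e+00 3.96264e+02
4.09564e+00 3.30214e+02 1.89992e-01 1.27668e+00 3.31680e+02
4.36672e+00 2.75981e+02 1.89796e-01 1.22525e+00 2.77396e+02
4.65573e+00 2.30446e+02 1.89587e-01 1.17342e+00 2.31809e+02
4.96387e+00 1.92249e+02 1.89366e-01 1.12112e+00 1.93559e+02
5.29241e+00 1.60237e+02 1.89130e-01 1.06832e+00 1.61494e+02
5.64269e+00 1.33433e+02 1.88879e-01 1.01504e+00 1.34637e+02
6.01616e+00 1.11011e+02 1.88613e-01 9.61349e-01 1.12161e+02
6.41434e+00 9.22727e+01 1.88331e-01 9.07408e-01 9.33685e+01
6.83888e+00 7.66204e+01 1.88031e-01 8.53437e-01 7.76618e+01
7.29151e+00 6.35496e+01 1.87712e-01 7.99730e-01 6.45371e+01
7.77410e+00 5.26715e+01 1.87374e-01 7.46639e-01 5.36055e+01
8.28864e+00 4.36247e+01 1.87015e-01 6.94548e-01 4.45063e+01
8.83723e+00 3.61063e+01 1.86634e-01 6.43852e-01 3.69368e+01
9.42212e+00 2.98191e+01 1.86231e-01 5.94929e-01 3.06003e+01
1.00457e+01 2.46096e+01 1.85803e-01 5.48114e-01 2.53435e+01
1.07106e+01 2.02999e+01 1.85350e-01 5.03679e-01 2.09890e+01
1.14195e+01 1.67364e+01 1.84870e-01 4.61818e-01 1.73831e+01
1.21753e+01 1.37915e+01 1.84362e-01 4.22644e-01 1.43985e+01
1.29811e+01 1.13589e+01 1.83825e-01 3.86191e-01 1.19289e+01
1.38403e+01 9.35052e+00 1.83256e-01 3.52426e-01 9.88620e+00
1.47563e+01 7.69331e+00 1.82655e-01 3.21259e-01 8.19723e+00
1.57330e+01 6.32655e+00 1.82019e-01 2.92568e-01 6.80114e+00
1.67743e+01 5.19991e+00 1.81348e-01 2.66206e-01 5.64746e+00
1.78845e+01 4.27169e+00 1.80640e-01 2.42022e-01 4.69435e+00
1.90682e+01 3.50734e+00 1.79893e-01 2.19866e-01 3.90710e+00
2.03302e+01 2.87826e+00 1.79106e-01 1.99600e-01 3.25696e+00
2.16758e+01 2.36078e+00 1.78276e-01 1.81096e-01 2.72015e+00
2.31104e+01 1.93533e+00 1.77403e-01 1.64238e-01 2.27697e+00
2.46400e+01 1.58572e+00 1.76485e-01 1.48920e-01 1.91113e+00
2.62708e+01 1.29859e+00 1.75520e-01 1.34600e-01 1.60871e+00
2.80096e+01 1.06276e+00 1.74506e-01 1.20961e-01 1.35823e+00
2.98634e+01 8.69328e-01 1.73443e-01 1.08337e-01 1.15111e+00
3.18400e+01 7.10774e-01 1.72328e-01 9.68373e-02 9.79939e-01
3.39473e+01 5.80873e-01 1.71160e-01 8.64536e-02 8.38487e-01
3.61941e+01 4.74496e-01 1.69939e-01 7.71214e-02 7.21556e-01
3.85897e+01 3.87423e-01 1.68662e-01 6.87544e-02 6.24839e-01
4.11437e+01 3.16183e-01 1.67330e-01 6.12612e-02 5.44774e-01
4.38669e+01 2.57926e-01 1.65940e-01 5.45543e-02 4.78420e-01
4.67702e+01 2.10306e-01 1.64493e-01 4.85532e-02 4.23352e-01
4.98657e+01 1.71400e-01 1.62988e-01 4.31853e-02 3.77573e-01
5.31661e+01 1.39627e-01 1.61424e-01 3.83858e-02 3.39437e-01
5.66850e+01 1.13692e-01 1.59801e-01 3.40966e-02 3.07590e-01
6.04367e+01 9.25323e-02 1.58120e-01 3.02660e-02 2.80919e-01
6.44367e+01 7.52761e-02 1.56381e-01 2.68475e-02 2.58505e-01
6.87015e+01 6.12099e-02 1.54585e-01 2.37992e-02 2.39594e-01
7.32486e+01 4.97494e-02 1.52732e-01 2.10834e-02 2.23565e-01
7.80966e+01 4.04161e-02 1.50823e-01 1.86661e-02 2.09905e-01
8.32654e+01 3.28188e-02 1.48861e-01 1.65162e-02 1.98196e-01
8.87764e+01 2.66374e-02 1.46846e-01 1.46060e-02 1.88090e-01
9.46521e+01 2.16104e-02 1.44782e-01 1.29102e-02 1.79302e-01
1.00917e+02 1.75241e-02 1.42669e-01 1.14059e-02 1.71599e-01
1.07596e+02 1.42039e-02 1.40511e-01 1.00725e-02 1.64788e-01
1.14717e+02 1.15075e-02 1.38311e-01 8.89142e-03 1.58710e-01
1.22310e+02 9.31874e-03 1.36071e-01 7.84601e-03 1.53236e-01
1.30405e+02 7.54282e-03 1.33795e-01 6.92124e-03 1.48259e-01
1.39036e+02 6.10255e-03 1.31486e-01 6.10366e-03 1.43692e-01
1.48238e+02 4.93503e-03 1.29148e-01 5.38120e-03 1.39464e-01
1.58049e+02 3.98906e-03 1.26784e-01 4.74312e-03 1.35516e-01
1.68510e+02 3.22294e-03 1.24398e-01 4.17978e-03 1.31801e-01
1.79663e+02 2.60276e-03 1.21994e-01 3.68264e-03 1.28280e-01
1.91554e+02 2.10097e-03 1.19576e-01 3.24406e-03 1.24921e-01
2.04232e+02 1.69514e-03 1.17148e-01 2.85726e-03 1.21700e-01
2.17749e+02 1.36707e-03 1.14713e-01 2.51623e-03 1.18596e-01
2.32161e+02 1.10200e-03 1.12274e-01 2.21564e-03 1.15592e-01
2.47527e+02 8.87913e-04 1.09836e-01 1.95073e-03 1.12674e-01
2.63910e+02 7.15093e-04 1.07401e-01 1.71733e-03 1.09834e-01
2.81377e+02 5.75647e-04 1.04973e-01 1.51173e-03 1.07061e-01
3.00000e+02 4.63181e-04 1.02555e-01 1.33063e-03 1.04349e-01
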