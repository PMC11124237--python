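# mass attenuation coefficients for Br (Z=35, A=79.9040)
# photoelectric: Cromer-Liberman f'' (gemmi 0.7.4); incoherent: Klein-Nishina free-electron; coherent: Thomson x IT92 form factor
# K-edge: 13.474 keV
# columns: energy_keV photoelectric incoherent coherent total  [cm^2/g]
1.00000e+00 2.39189e+03 1.74799e-01 5.83357e+00 2.39790e+03
1.06619e+00 2.05474e+03 1.74754e-01 5.79541e+00 2.06071e+03
1.13675e+00 1.76356e+03 1.74706e-01 5.75300e+00 1.76949e+03
1.21199e+00 1.51240e+03 1.74655e-01 5.70601e+00 1.51828e+03
1.29220e+00 1.29594e+03 1.74600e-01 5.65408e+00 1.30177e+03
1.37773e+00 1.10861e+03 1.74542e-01 5.59691e+00 1.11439e+03
1.46892e+00 9.47648e+02 1.74481e-01 5.53420e+00 9.53356e+02
1.56614e+00 9.03758e+03 1.74415e-01 5.46569e+00 9.04322e+03
1.66979e+00 4.67131e+03 1.74345e-01 5.39117e+00 4.67687e+03
1.78031e+00 3.88636e+03 1.74270e-01 5.31050e+00 3.89184e+03
1.89814e+00 3.79736e+03 1.74191e-01 5.22363e+00 3.80275e+03
2.02377e+00 3.24221e+03 1.74106e-01 5.13058e+00 3.24751e+03
2.15771e+00 2.76727e+03 1.74016e-01 5.03148e+00 2.77248e+03
2.30052e+00 2.35894e+03 1.73920e-01 4.92656e+00 2.36405e+03
2.45279e+00 2.00788e+03 1.73818e-01 4.81614e+00 2.01287e+03
2.61512e+00 1.70679e+03 1.73709e-01 4.70064e+00 1.71166e+03
2.78821e+00 1.44897e+03 1.73594e-01 4.58055e+00 1.45373e+03
2.97275e+00 1.22853e+03 1.73471e-01 4.45639e+00 1.23316e+03
3.16950e+00 1.03998e+03 1.73340e-01 4.32873e+00 1.04448e+03
3.37928e+00 8.78991e+02 1.73200e-01 4.19811e+00 8.83362e+02
3.60294e+00 7.42210e+02 1.73052e-01 4.06505e+00 7.46448e+02
3.84140e+00 6.26061e+02 1.72894e-01 3.93001e+00 6.30164e+02
4.09564e+00 5.27729e+02 1.72726e-01 3.79337e+00 5.31695e+02
4.36672e+00 4.44543e+02 1.72548e-01 3.65545e+00 4.48371e+02
4.65573e+00 3.74223e+02 1.72358e-01 3.51651e+00 3.77912e+02
4.96387e+00 3.14822e+02 1.72157e-01 3.37672e+00 3.18371e+02
5.29241e+00 2.64682e+02 1.71942e-01 3.23625e+00 2.68090e+02
5.64269e+00 2.22386e+02 1.71715e-01 3.09519e+00 2.25653e+02
6.01616e+00 1.86733e+02 1.71473e-01 2.95366e+00 1.89858e+02
6.41434e+00 1.56699e+02 1.71216e-01 2.81178e+00 1.59682e+02
6.83888e+00 1.31409e+02 1.70943e-01 2.66972e+00 1.34249e+02
7.29151e+00 1.10119e+02 1.70653e-01 2.52773e+00 1.12817e+02
7.77410e+00 9.22314e+01 1.70346e-01 2.38618e+00 9.47879e+01
8.28864e+00 7.72094e+01 1.70020e-01 2.24558e+00 7.96250e+01
8.83723e+00 6.46081e+01 1.69674e-01 2.10658e+00 6.68844e+01
9.42212e+00 5.39448e+01 1.69307e-01 1.96995e+00 5.60840e+01
1.00457e+01 4.50242e+01 1.68918e-01 1.83653e+00 4.70296e+01
1.07106e+01 3.75730e+01 1.68506e-01 1.70720e+00 3.94487e+01
1.14195e+01 3.13497e+01 1.68070e-01 1.58278e+00 3.31006e+01
1.21753e+01 2.61527e+01 1.67608e-01 1.46402e+00 2.77843e+01
1.29811e+01 2.18130e+01 1.67119e-01 1.35147e+00 2.33316e+01
1.34605e+01 1.96829e+01 1.66830e-01 1.29069e+00 2.11404e+01
1.34875e+01 1.48966e+02 1.66814e-01 1.28741e+00 1.50421e+02
1.38403e+01 1.37583e+02 1.66602e-01 1.24553e+00 1.38995e+02
1.47563e+01 1.15535e+02 1.66056e-01 1.14641e+00 1.16848e+02
1.57330e+01 9.77672e+01 1.65478e-01 1.05411e+00 9.89868e+01
1.67743e+01 8.26234e+01 1.64868e-01 9.68469e-01 8.37567e+01
1.78845e+01 6.97153e+01 1.64224e-01 8.89212e-01 7.07688e+01
1.90682e+01 5.87242e+01 1.63545e-01 8.15954e-01 5.97037e+01
2.03302e+01 4.94121e+01 1.62829e-01 7.48264e-01 5.03232e+01
2.16758e+01 4.15313e+01 1.62075e-01 6.85702e-01 4.23791e+01
2.31104e+01 3.48690e+01 1.61282e-01 6.27850e-01 3.56581e+01
2.46400e+01 2.92431e+01 1.60447e-01 5.74333e-01 2.99779e+01
2.62708e+01 2.44977e+01 1.59569e-01 5.22810e-01 2.51800e+01
2.80096e+01 2.04885e+01 1.58648e-01 4.72307e-01 2.11195e+01
2.98634e+01 1.71162e+01 1.57681e-01 4.24858e-01 1.76987e+01
3.18400e+01 1.42885e+01 1.56667e-01 3.81270e-01 1.48265e+01
3.39473e+01 1.19194e+01 1.55606e-01 3.41696e-01 1.24167e+01
3.61941e+01 9.93572e+00 1.54495e-01 3.05974e-01 1.03962e+01
3.85897e+01 8.27610e+00 1.53335e-01 2.73815e-01 8.70325e+00
4.11437e+01 6.88858e+00 1.52123e-01 2.44893e-01 7.28560e+00
4.38669e+01 5.72941e+00 1.50860e-01 2.18889e-01 6.09916e+00
4.67702e+01 4.76173e+00 1.49544e-01 1.95509e-01 5.10678e+00
4.98657e+01 3.95451e+00 1.48176e-01 1.74492e-01 4.27718e+00
5.31661e+01 3.28165e+00 1.46754e-01 1.55605e-01 3.58401e+00
5.66850e+01 2.72121e+00 1.45279e-01 1.38641e-01 3.00513e+00
6.04367e+01 2.25357e+00 1.43751e-01 1.23417e-01 2.52074e+00
6.44367e+01 1.86466e+00 1.42170e-01 1.09766e-01 2.11660e+00
6.87015e+01 1.54238e+00 1.40537e-01 9.75401e-02 1.78045e+00
7.32486e+01 1.27539e+00 1.38852e-01 8.66021e-02 1.50084e+00
7.80966e+01 1.05428e+00 1.37117e-01 7.68281e-02 1.26822e+00
8.32654e+01 8.71215e-01 1.35333e-01 6.81049e-02 1.07465e+00
8.87764e+01 7.19706e-01 1.33501e-01 6.03285e-02 9.13536e-01
9.46521e+01 5.94351e-01 1.31624e-01 5.34041e-02 7.79379e-01
1.00917e+02 4.90668e-01 1.29704e-01 4.72451e-02 6.67617e-01
1.07596e+02 4.04940e-01 1.27742e-01 4.17725e-02 5.74454e-01
1.14717e+02 3.34079e-01 1.25742e-01 3.69146e-02 4.96735e-01
1.22310e+02 2.75527e-01 1.23705e-01 3.26060e-02 4.31838e-01
1.30405e+02 2.27162e-01 1.21636e-01 2.87879e-02 3.77586e-01
1.39036e+02 1.87225e-01 1.19537e-01 2.54069e-02 3.32168e-01
1.48238e+02 1.54257e-01 1.17411e-01 2.24150e-02 2.94084e-01
1.58049e+02 1.27053e-01 1.15262e-01 1.97692e-02 2.62084e-01
1.68510e+02 1.04612e-01 1.13093e-01 1.74307e-02 2.35136e-01
1.79663e+02 8.61056e-02 1.10908e-01 1.53650e-02 2.12379e-01
1.91554e+02 7.08499e-02 1.08710e-01 1.35409e-02 1.93100e-01
2.04232e+02 5.82779e-02 1.06502e-01 1.19309e-02 1.76711e-01
2.17749e+02 4.79209e-02 1.04288e-01 1.05104e-02 1.62719e-01
2.32161e+02 3.93917e-02 1.02071e-01 9.25759e-03 1.50720e-01
2.47527e+02 3.23700e-02 9.98543e-02 8.15290e-03 1.40377e-01
2.63910e+02 2.65912e-02 9.76409e-02 7.17912e-03 1.31411e-01
2.81377e+02 2.18371e-02 9.54335e-02 6.32091e-03 1.23592e-01
3.00000e+02 1.79271e-02 9.32350e-02 5.56474e-03 1.16727e-01
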