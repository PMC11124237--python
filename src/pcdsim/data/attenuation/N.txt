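# mass attenuation coefficients for N (Z=7, A=14.0067)
# photoelectric: Cromer-Liberman f'' (gemmi 0.7.4); incoherent: Klein-Nishina free-electron; coherent: Thomson x IT92 form factor
# K-edge: none keV
# columns: energy_keV photoelectric incoherent coherent total  [cm^2/g]
1.00000e+00 3.16934e+03 1.99435e-01 1.29083e+00 3.17083e+03
1.06619e+00 2.66012e+03 1.99383e-01 1.27725e+00 2.66160e+03
1.13675e+00 2.23059e+03 1.99329e-01 1.26215e+00 2.23205e+03
1.21199e+00 1.86863e+03 1.99270e-01 1.24541e+00 1.87008e+03
1.29220e+00 1.56392e+03 1.99208e-01 1.22690e+00 1.56535e+03
1.37773e+00 1.30765e+03 1.99142e-01 1.20651e+00 1.30905e+03
1.46892e+00 1.09233e+03 1.99072e-01 1.18414e+00 1.09371e+03
1.56614e+00 9.11591e+02 1.98997e-01 1.15971e+00 9.12950e+02
1.66979e+00 7.59654e+02 1.98917e-01 1.13314e+00 7.60986e+02
1.78031e+00 6.32321e+02 1.98832e-01 1.10440e+00 6.33625e+02
1.89814e+00 5.25924e+02 1.98741e-01 1.07349e+00 5.27196e+02
2.02377e+00 4.37090e+02 1.98645e-01 1.04046e+00 4.38329e+02
2.15771e+00 3.62979e+02 1.98542e-01 1.00539e+00 3.64183e+02
2.30052e+00 3.01200e+02 1.98433e-01 9.68429e-01 3.02367e+02
2.45279e+00 2.49741e+02 1.98316e-01 9.29768e-01 2.50870e+02
2.61512e+00 2.06913e+02 1.98192e-01 8.89655e-01 2.08001e+02
2.78821e+00 1.71297e+02 1.98060e-01 8.48382e-01 1.72343e+02
2.97275e+00 1.41700e+02 1.97920e-01 8.06280e-01 1.42704e+02
3.16950e+00 1.17039e+02 1.97770e-01 7.63707e-01 1.18001e+02
3.37928e+00 9.65940e+01 1.97611e-01 7.21032e-01 9.75126e+01
3.60294e+00 7.96683e+01 1.97442e-01 6.78621e-01 8.05444e+01
3.84140e+00 6.56655e+01 1.97262e-01 6.36823e-01 6.64996e+01
4.09564e+00 5.40884e+01 1.97071e-01 5.95956e-01 5.48815e+01
4.36672e+00 4.45233e+01 1.96867e-01 5.56298e-01 4.52765e+01
4.65573e+00 3.66257e+01 1.96651e-01 5.18083e-01 3.73404e+01
4.96387e+00 3.01093e+01 1.96420e-01 4.81498e-01 3.07872e+01
5.29241e+00 2.47360e+01 1.96176e-01 4.46686e-01 2.53789e+01
5.64269e+00 2.03084e+01 1.95916e-01 4.13749e-01 2.09181e+01
6.01616e+00 1.66624e+01 1.95640e-01 3.82753e-01 1.72408e+01
6.41434e+00 1.36620e+01 1.95347e-01 3.53728e-01 1.42111e+01
6.83888e+00 1.11945e+01 1.95036e-01 3.26671e-01 1.17162e+01
7.29151e+00 9.16670e+00 1.94705e-01 3.01550e-01 9.66295e+00
7.77410e+00 7.50070e+00 1.94354e-01 2.78301e-01 7.97336e+00
8.28864e+00 6.13364e+00 1.93982e-01 2.56831e-01 6.58446e+00
8.83723e+00 5.01322e+00 1.93588e-01 2.37030e-01 5.44383e+00
9.42212e+00 4.08943e+00 1.93169e-01 2.18766e-01 4.50136e+00
1.00457e+01 3.33428e+00 1.92725e-01 2.01903e-01 3.72891e+00
1.07106e+01 2.71781e+00 1.92255e-01 1.86306e-01 3.09637e+00
1.14195e+01 2.21469e+00 1.91758e-01 1.71845e-01 2.57829e+00
1.21753e+01 1.80419e+00 1.91231e-01 1.58405e-01 2.15383e+00
1.29811e+01 1.46936e+00 1.90673e-01 1.45885e-01 1.80592e+00
1.38403e+01 1.19633e+00 1.90083e-01 1.34201e-01 1.52061e+00
1.47563e+01 9.73757e-01 1.89459e-01 1.23281e-01 1.28650e+00
1.57330e+01 7.92370e-01 1.88800e-01 1.13068e-01 1.09424e+00
1.67743e+01 6.44588e-01 1.88104e-01 1.03515e-01 9.36208e-01
1.78845e+01 5.24221e-01 1.87370e-01 9.45844e-02 8.06175e-01
1.90682e+01 4.26210e-01 1.86595e-01 8.62449e-02 6.99050e-01
2.03302e+01 3.46426e-01 1.85778e-01 7.84713e-02 6.10675e-01
2.16758e+01 2.81497e-01 1.84918e-01 7.12416e-02 5.37657e-01
2.31104e+01 2.28673e-01 1.84013e-01 6.45352e-02 4.77221e-01
2.46400e+01 1.85709e-01 1.83060e-01 5.83315e-02 4.27100e-01
2.62708e+01 1.50775e-01 1.82059e-01 5.25591e-02 3.85393e-01
2.80096e+01 1.22193e-01 1.81007e-01 4.72046e-02 3.50405e-01
2.98634e+01 9.89726e-02 1.79904e-01 4.23173e-02 3.21194e-01
3.18400e+01 8.01618e-02 1.78748e-01 3.78945e-02 2.96804e-01
3.39473e+01 6.49239e-02 1.77537e-01 3.39085e-02 2.76369e-01
3.61941e+01 5.25807e-02 1.76270e-01 3.03229e-02 2.59173e-01
3.85897e+01 4.25826e-02 1.74946e-01 2.70998e-02 2.44628e-01
4.11437e+01 3.44843e-02 1.73564e-01 2.42032e-02 2.32251e-01
4.38669e+01 2.79251e-02 1.72122e-01 2.16005e-02 2.21648e-01
4.67702e+01 2.26127e-02 1.70621e-01 1.92625e-02 2.12496e-01
4.98657e+01 1.83103e-02 1.69060e-01 1.71632e-02 2.04533e-01
5.31661e+01 1.48259e-02 1.67438e-01 1.52796e-02 1.97543e-01
5.66850e+01 1.20041e-02 1.65755e-01 1.35909e-02 1.91350e-01
6.04367e+01 9.71906e-03 1.64011e-01 1.20785e-02 1.85809e-01
6.44367e+01 7.86868e-03 1.62207e-01 1.07253e-02 1.80801e-01
6.87015e+01 6.37034e-03 1.60344e-01 9.51613e-03 1.76230e-01
7.32486e+01 5.15712e-03 1.58422e-01 8.43676e-03 1.72016e-01
7.80966e+01 4.17480e-03 1.56442e-01 7.47442e-03 1.68091e-01
8.32654e+01 3.37947e-03 1.54407e-01 6.61738e-03 1.64404e-01
8.87764e+01 2.73554e-03 1.52317e-01 5.85494e-03 1.60908e-01
9.46521e+01 2.21423e-03 1.50175e-01 5.17735e-03 1.57567e-01
1.00917e+02 1.79219e-03 1.47984e-01 4.57575e-03 1.54352e-01
1.07596e+02 1.45054e-03 1.45746e-01 4.04210e-03 1.51239e-01
1.14717e+02 1.17398e-03 1.43464e-01 3.56911e-03 1.48207e-01
1.22310e+02 9.50109e-04 1.41140e-01 3.15021e-03 1.45241e-01
1.30405e+02 7.68900e-04 1.38779e-01 2.77947e-03 1.42328e-01
1.39036e+02 6.22228e-04 1.36384e-01 2.45157e-03 1.39458e-01
1.48238e+02 5.03515e-04 1.33959e-01 2.16172e-03 1.36624e-01
1.58049e+02 4.07435e-04 1.31507e-01 1.90564e-03 1.33820e-01
1.68510e+02 3.29677e-04 1.29033e-01 1.67950e-03 1.31042e-01
1.79663e+02 2.66748e-04 1.26539e-01 1.47988e-03 1.28286e-01
1.91554e+02 2.15823e-04 1.24031e-01 1.30374e-03 1.25551e-01
2.04232e+02 1.74613e-04 1.21512e-01 1.14838e-03 1.22835e-01
2.17749e+02 1.41267e-04 1.18986e-01 1.01138e-03 1.20139e-01
2.32161e+02 1.14284e-04 1.16457e-01 8.90605e-04 1.17462e-01
2.47527e+02 9.24519e-05 1.13928e-01 7.84161e-04 1.14804e-01
2.63910e+02 7.47875e-05 1.11402e-01 6.90366e-04 1.12167e-01
2.81377e+02 6.04958e-05 1.08884e-01 6.07734e-04 1.09552e-01
3.00000e+02 4.89333e-05 1.06376e-01 5.34948e-04 1.06959e-01
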