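# mass attenuation coefficients for O (Z=8, A=15.9994)
# photoelectric: Cromer-Liberman f'' (gemmi 0.7.4); incoherent: Klein-Nishina free-electron; coherent: Thomson x IT92 form factor
# K-edge: none keV
# columns: energy_keV photoelectric incoherent coherent total  [cm^2/g]
1.00000e+00 4.41904e+03 1.99538e-01 1.50146e+00 4.42074e+03
1.06619e+00 3.72813e+03 1.99486e-01 1.48864e+00 3.72981e+03
1.13675e+00 3.14189e+03 1.99432e-01 1.47434e+00 3.14356e+03
1.21199e+00 2.64502e+03 1.99373e-01 1.45841e+00 2.64668e+03
1.29220e+00 2.22436e+03 1.99311e-01 1.44072e+00 2.22600e+03
1.37773e+00 1.86861e+03 1.99245e-01 1.42112e+00 1.87023e+03
1.46892e+00 1.56808e+03 1.99175e-01 1.39950e+00 1.56968e+03
1.56614e+00 1.31449e+03 1.99100e-01 1.37571e+00 1.31606e+03
1.66979e+00 1.10073e+03 1.99020e-01 1.34964e+00 1.10227e+03
1.78031e+00 9.20745e+02 1.98934e-01 1.32122e+00 9.22265e+02
1.89814e+00 7.69370e+02 1.98844e-01 1.29035e+00 7.70859e+02
2.02377e+00 6.42195e+02 1.98747e-01 1.25702e+00 6.43651e+02
2.15771e+00 5.35388e+02 1.98644e-01 1.22123e+00 5.36808e+02
2.30052e+00 4.45698e+02 1.98535e-01 1.18303e+00 4.47079e+02
2.45279e+00 3.70736e+02 1.98418e-01 1.14252e+00 3.72077e+02
2.61512e+00 3.08136e+02 1.98294e-01 1.09986e+00 3.09434e+02
2.78821e+00 2.55901e+02 1.98162e-01 1.05527e+00 2.57155e+02
2.97275e+00 2.12352e+02 1.98022e-01 1.00901e+00 2.13559e+02
3.16950e+00 1.75924e+02 1.97872e-01 9.61409e-01 1.77084e+02
3.37928e+00 1.45625e+02 1.97713e-01 9.12827e-01 1.46735e+02
3.60294e+00 1.20462e+02 1.97544e-01 8.63656e-01 1.21523e+02
3.84140e+00 9.95792e+01 1.97364e-01 8.14309e-01 1.00591e+02
4.09564e+00 8.22608e+01 1.97172e-01 7.65203e-01 8.32232e+01
4.36672e+00 6.79082e+01 1.96969e-01 7.16747e-01 6.88219e+01
4.65573e+00 5.60217e+01 1.96752e-01 6.69324e-01 5.68877e+01
4.96387e+00 4.61843e+01 1.96522e-01 6.23282e-01 4.70041e+01
5.29241e+00 3.80484e+01 1.96277e-01 5.78924e-01 3.88236e+01
5.64269e+00 3.13244e+01 1.96017e-01 5.36495e-01 3.20569e+01
6.01616e+00 2.57710e+01 1.95741e-01 4.96184e-01 2.64629e+01
6.41434e+00 2.11877e+01 1.95448e-01 4.58119e-01 2.18413e+01
6.83888e+00 1.74077e+01 1.95136e-01 4.22369e-01 1.80252e+01
7.29151e+00 1.42922e+01 1.94806e-01 3.88953e-01 1.48760e+01
7.77410e+00 1.17264e+01 1.94455e-01 3.57845e-01 1.22787e+01
8.28864e+00 9.61453e+00 1.94082e-01 3.28984e-01 1.01376e+01
8.83723e+00 7.87764e+00 1.93687e-01 3.02285e-01 8.37361e+00
9.42212e+00 6.44952e+00 1.93269e-01 2.77641e-01 6.92043e+00
1.00457e+01 5.27695e+00 1.92825e-01 2.54935e-01 5.72471e+00
1.07106e+01 4.31062e+00 1.92355e-01 2.34038e-01 4.73701e+00
1.14195e+01 3.51999e+00 1.91857e-01 2.14817e-01 3.92667e+00
1.21753e+01 2.87344e+00 1.91329e-01 1.97134e-01 3.26190e+00
1.29811e+01 2.34489e+00 1.90771e-01 1.80854e-01 2.71651e+00
1.38403e+01 1.91294e+00 1.90181e-01 1.65844e-01 2.26896e+00
1.47563e+01 1.56005e+00 1.89557e-01 1.51982e-01 1.90159e+00
1.57330e+01 1.27185e+00 1.88898e-01 1.39159e-01 1.59991e+00
1.67743e+01 1.03656e+00 1.88202e-01 1.27278e-01 1.35204e+00
1.78845e+01 8.44520e-01 1.87467e-01 1.16257e-01 1.14824e+00
1.90682e+01 6.87837e-01 1.86691e-01 1.06026e-01 9.80554e-01
2.03302e+01 5.60040e-01 1.85874e-01 9.65310e-02 8.42446e-01
2.16758e+01 4.55840e-01 1.85014e-01 8.77243e-02 7.28578e-01
2.31104e+01 3.70906e-01 1.84107e-01 7.95687e-02 6.34583e-01
2.46400e+01 3.01700e-01 1.83154e-01 7.20330e-02 5.56887e-01
2.62708e+01 2.45327e-01 1.82153e-01 6.49764e-02 4.92456e-01
2.80096e+01 1.99110e-01 1.81101e-01 5.83560e-02 4.38567e-01
2.98634e+01 1.61498e-01 1.79997e-01 5.22847e-02 3.93779e-01
3.18400e+01 1.30982e-01 1.78840e-01 4.67840e-02 3.56606e-01
3.39473e+01 1.06225e-01 1.77628e-01 4.18304e-02 3.25683e-01
3.61941e+01 8.61409e-02 1.76361e-01 3.73817e-02 2.99883e-01
3.85897e+01 6.98497e-02 1.75036e-01 3.33904e-02 2.78276e-01
4.11437e+01 5.66356e-02 1.73653e-01 2.98102e-02 2.60099e-01
4.38669e+01 4.59181e-02 1.72211e-01 2.65985e-02 2.44728e-01
4.67702e+01 3.72262e-02 1.70709e-01 2.37172e-02 2.31653e-01
4.98657e+01 3.01775e-02 1.69147e-01 2.11327e-02 2.20457e-01
5.31661e+01 2.44618e-02 1.67524e-01 1.88153e-02 2.10801e-01
5.66850e+01 1.98272e-02 1.65840e-01 1.67386e-02 2.02406e-01
6.04367e+01 1.60696e-02 1.64096e-01 1.48790e-02 1.95044e-01
6.44367e+01 1.30233e-02 1.62291e-01 1.32153e-02 1.88530e-01
6.87015e+01 1.05536e-02 1.60427e-01 1.17283e-02 1.82709e-01
7.32486e+01 8.55175e-03 1.58504e-01 1.04008e-02 1.77456e-01
7.80966e+01 6.92910e-03 1.56523e-01 9.21690e-03 1.72669e-01
8.32654e+01 5.61394e-03 1.54486e-01 8.16219e-03 1.68263e-01
8.87764e+01 4.54808e-03 1.52396e-01 7.22357e-03 1.64167e-01
9.46521e+01 3.68433e-03 1.50253e-01 6.38912e-03 1.60326e-01
1.00917e+02 2.98440e-03 1.48061e-01 5.64798e-03 1.56693e-01
1.07596e+02 2.41727e-03 1.45821e-01 4.99033e-03 1.53229e-01
1.14717e+02 1.95777e-03 1.43538e-01 4.40724e-03 1.49903e-01
1.22310e+02 1.58551e-03 1.41213e-01 3.89066e-03 1.46689e-01
1.30405e+02 1.28394e-03 1.38851e-01 3.43335e-03 1.43568e-01
1.39036e+02 1.03966e-03 1.36455e-01 3.02876e-03 1.40523e-01
1.48238e+02 8.41791e-04 1.34028e-01 2.67102e-03 1.37541e-01
1.58049e+02 6.81534e-04 1.31575e-01 2.35489e-03 1.34611e-01
1.68510e+02 5.51747e-04 1.29099e-01 2.07567e-03 1.31727e-01
1.79663e+02 4.46644e-04 1.26605e-01 1.82915e-03 1.28880e-01
1.91554e+02 3.61536e-04 1.24095e-01 1.61159e-03 1.26068e-01
2.04232e+02 2.92625e-04 1.21575e-01 1.41965e-03 1.23287e-01
2.17749e+02 2.36832e-04 1.19048e-01 1.25038e-03 1.20535e-01
2.32161e+02 1.91664e-04 1.16517e-01 1.10113e-03 1.17810e-01
2.47527e+02 1.55098e-04 1.13987e-01 9.69582e-04 1.15111e-01
2.63910e+02 1.25500e-04 1.11460e-01 8.53653e-04 1.12439e-01
2.81377e+02 1.01543e-04 1.08940e-01 7.51510e-04 1.09793e-01
3.00000e+02 8.21534e-05 1.06430e-01 6.61532e-04 1.07174e-01
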