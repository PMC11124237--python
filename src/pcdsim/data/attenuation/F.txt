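# mass attenuation coefficients for F (Z=9, A=18.9984)
# photoelectric: Cromer-Liberman f'' (gemmi 0.7.4); incoherent: Klein-Nishina free-electron; coherent: Thomson x IT92 form factor
# K-edge: none keV
# columns: energy_keV photoelectric incoherent coherent total  [cm^2/g]
1.00000e+00 5.52579e+03 1.89044e-01 1.61998e+00 5.52760e+03
1.06619e+00 4.69698e+03 1.88996e-01 1.60867e+00 4.69878e+03
1.13675e+00 3.98643e+03 1.88944e-01 1.59599e+00 3.98822e+03
1.21199e+00 3.37203e+03 1.88889e-01 1.58182e+00 3.37380e+03
1.29220e+00 2.84681e+03 1.88830e-01 1.56601e+00 2.84856e+03
1.37773e+00 2.40071e+03 1.88767e-01 1.54841e+00 2.40245e+03
1.46892e+00 2.02226e+03 1.88701e-01 1.52889e+00 2.02397e+03
1.56614e+00 1.70156e+03 1.88629e-01 1.50729e+00 1.70326e+03
1.66979e+00 1.43012e+03 1.88554e-01 1.48346e+00 1.43179e+03
1.78031e+00 1.20064e+03 1.88473e-01 1.45728e+00 1.20228e+03
1.89814e+00 1.00685e+03 1.88387e-01 1.42863e+00 1.00846e+03
2.02377e+00 8.43387e+02 1.88296e-01 1.39741e+00 8.44972e+02
2.15771e+00 7.05671e+02 1.88198e-01 1.36357e+00 7.07223e+02
2.30052e+00 5.89779e+02 1.88094e-01 1.32708e+00 5.91294e+02
2.45279e+00 4.92365e+02 1.87984e-01 1.28795e+00 4.93841e+02
2.61512e+00 4.10579e+02 1.87867e-01 1.24625e+00 4.12013e+02
2.78821e+00 3.41975e+02 1.87741e-01 1.20211e+00 3.43365e+02
2.97275e+00 2.84532e+02 1.87608e-01 1.15572e+00 2.85876e+02
3.16950e+00 2.36359e+02 1.87467e-01 1.10732e+00 2.37654e+02
3.37928e+00 1.96178e+02 1.87316e-01 1.05722e+00 1.97422e+02
3.60294e+00 1.62712e+02 1.87155e-01 1.00576e+00 1.63905e+02
3.84140e+00 1.34861e+02 1.86985e-01 9.53348e-01 1.36002e+02
4.09564e+00 1.11698e+02 1.86803e-01 9.00410e-01 1.12785e+02
4.36672e+00 9.24477e+01 1.86610e-01 8.47393e-01 9.34818e+01
4.65573e+00 7.64616e+01 1.86405e-01 7.94742e-01 7.74427e+01
4.96387e+00 6.31954e+01 1.86187e-01 7.42892e-01 6.41245e+01
5.29241e+00 5.21942e+01 1.85955e-01 6.92248e-01 5.30724e+01
5.64269e+00 4.30777e+01 1.85709e-01 6.43175e-01 4.39066e+01
6.01616e+00 3.55286e+01 1.85448e-01 5.95987e-01 3.63100e+01
6.41434e+00 2.92817e+01 1.85170e-01 5.50938e-01 3.00178e+01
6.83888e+00 2.41161e+01 1.84875e-01 5.08216e-01 2.48092e+01
7.29151e+00 1.98478e+01 1.84561e-01 4.67946e-01 2.05003e+01
7.77410e+00 1.63234e+01 1.84229e-01 4.30192e-01 1.69378e+01
8.28864e+00 1.34153e+01 1.83876e-01 3.94962e-01 1.39941e+01
8.83723e+00 1.10175e+01 1.83502e-01 3.62219e-01 1.15632e+01
9.42212e+00 9.03755e+00 1.83105e-01 3.31893e-01 9.55255e+00
1.00457e+01 7.40920e+00 1.82685e-01 3.03884e-01 7.89577e+00
1.07106e+01 6.07122e+00 1.82239e-01 2.78080e-01 6.53154e+00
1.14195e+01 4.97237e+00 1.81767e-01 2.54354e-01 5.40849e+00
1.21753e+01 4.07038e+00 1.81268e-01 2.32570e-01 4.48422e+00
1.29811e+01 3.32998e+00 1.80739e-01 2.12588e-01 3.72331e+00
1.38403e+01 2.72115e+00 1.80180e-01 1.94265e-01 3.09560e+00
1.47563e+01 2.22286e+00 1.79589e-01 1.77460e-01 2.57991e+00
1.57330e+01 1.81518e+00 1.78964e-01 1.62034e-01 2.15618e+00
1.67743e+01 1.48175e+00 1.78305e-01 1.47859e-01 1.80791e+00
1.78845e+01 1.20914e+00 1.77608e-01 1.34817e-01 1.52156e+00
1.90682e+01 9.86335e-01 1.76874e-01 1.22803e-01 1.28601e+00
2.03302e+01 8.04304e-01 1.76100e-01 1.11728e-01 1.09213e+00
2.16758e+01 6.55637e-01 1.75284e-01 1.01514e-01 9.32435e-01
2.31104e+01 5.34262e-01 1.74426e-01 9.20958e-02 8.00783e-01
2.46400e+01 4.35202e-01 1.73523e-01 8.34183e-02 6.92143e-01
2.62708e+01 3.54385e-01 1.72574e-01 7.52681e-02 6.02227e-01
2.80096e+01 2.87857e-01 1.71577e-01 6.75720e-02 5.27006e-01
2.98634e+01 2.33639e-01 1.70531e-01 6.04949e-02 4.64665e-01
3.18400e+01 1.89632e-01 1.69435e-01 5.40791e-02 4.13146e-01
3.39473e+01 1.53914e-01 1.68287e-01 4.83051e-02 3.70506e-01
3.61941e+01 1.24923e-01 1.67086e-01 4.31264e-02 3.35136e-01
3.85897e+01 1.01392e-01 1.65831e-01 3.84877e-02 3.05711e-01
4.11437e+01 8.22933e-02 1.64521e-01 3.43339e-02 2.81148e-01
4.38669e+01 6.67919e-02 1.63155e-01 3.06138e-02 2.60561e-01
4.67702e+01 5.42102e-02 1.61732e-01 2.72815e-02 2.43224e-01
4.98657e+01 4.39983e-02 1.60252e-01 2.42966e-02 2.28547e-01
5.31661e+01 3.57099e-02 1.58714e-01 2.16234e-02 2.16048e-01
5.66850e+01 2.89827e-02 1.57119e-01 1.92302e-02 2.05332e-01
6.04367e+01 2.35227e-02 1.55466e-01 1.70891e-02 1.96078e-01
6.44367e+01 1.90912e-02 1.53757e-01 1.51748e-02 1.88023e-01
6.87015e+01 1.54944e-02 1.51990e-01 1.34650e-02 1.80950e-01
7.32486e+01 1.25752e-02 1.50168e-01 1.19391e-02 1.74683e-01
7.80966e+01 1.02059e-02 1.48292e-01 1.05789e-02 1.69077e-01
8.32654e+01 8.28301e-03 1.46362e-01 9.36746e-03 1.64013e-01
8.87764e+01 6.72234e-03 1.44382e-01 8.28963e-03 1.59394e-01
9.46521e+01 5.45569e-03 1.42352e-01 7.33161e-03 1.55139e-01
1.00917e+02 4.42768e-03 1.40274e-01 6.48086e-03 1.51183e-01
1.07596e+02 3.59336e-03 1.38153e-01 5.72603e-03 1.47472e-01
1.14717e+02 2.91623e-03 1.35989e-01 5.05684e-03 1.43962e-01
1.22310e+02 2.36668e-03 1.33787e-01 4.46404e-03 1.40618e-01
1.30405e+02 1.92068e-03 1.31549e-01 3.93927e-03 1.37409e-01
1.39036e+02 1.55872e-03 1.29279e-01 3.47502e-03 1.34313e-01
1.48238e+02 1.26497e-03 1.26980e-01 3.06455e-03 1.31309e-01
1.58049e+02 1.02657e-03 1.24656e-01 2.70183e-03 1.28384e-01
1.68510e+02 8.33094e-04 1.22310e-01 2.38146e-03 1.25525e-01
1.79663e+02 6.76079e-04 1.19947e-01 2.09862e-03 1.22721e-01
1.91554e+02 5.48654e-04 1.17569e-01 1.84900e-03 1.19967e-01
2.04232e+02 4.45243e-04 1.15182e-01 1.62879e-03 1.17256e-01
2.17749e+02 3.61322e-04 1.12787e-01 1.43458e-03 1.14583e-01
2.32161e+02 2.93217e-04 1.10390e-01 1.26335e-03 1.11946e-01
2.47527e+02 2.37948e-04 1.07992e-01 1.11242e-03 1.09343e-01
2.63910e+02 1.93097e-04 1.05598e-01 9.79413e-04 1.06771e-01
2.81377e+02 1.56698e-04 1.03211e-01 8.62223e-04 1.04230e-01
3.00000e+02 1.27161e-04 1.00834e-01 7.58990e-04 1.01720e-01
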