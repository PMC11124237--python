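# mass attenuation coefficients for Be (Z=4, A=9.0122)
# photoelectric: Cromer-Liberman f'' (gemmi 0.7.4); incoherent: Klein-Nishina free-electron; coherent: Thomson x IT92 form factor
# K-edge: none keV
# columns: energy_keV photoelectric incoherent coherent total  [cm^2/g]
1.00000e+00 5.48867e+02 1.77120e-01 5.91568e-01 5.49636e+02
1.06619e+00 4.54134e+02 1.77075e-01 5.78688e-01 4.54890e+02
1.13675e+00 3.75457e+02 1.77026e-01 5.64842e-01 3.76199e+02
1.21199e+00 3.10168e+02 1.76975e-01 5.50047e-01 3.10895e+02
1.29220e+00 2.56032e+02 1.76919e-01 5.34343e-01 2.56743e+02
1.37773e+00 2.11179e+02 1.76861e-01 5.17790e-01 2.11874e+02
1.46892e+00 1.74048e+02 1.76798e-01 5.00471e-01 1.74725e+02
1.56614e+00 1.43333e+02 1.76732e-01 4.82492e-01 1.43992e+02
1.66979e+00 1.17946e+02 1.76661e-01 4.63978e-01 1.18587e+02
1.78031e+00 9.69797e+01 1.76585e-01 4.45071e-01 9.76014e+01
1.89814e+00 7.96780e+01 1.76504e-01 4.25928e-01 8.02805e+01
2.02377e+00 6.54118e+01 1.76419e-01 4.06710e-01 6.59949e+01
2.15771e+00 5.36438e+01 1.76328e-01 3.87581e-01 5.42077e+01
2.30052e+00 4.39551e+01 1.76230e-01 3.68699e-01 4.45000e+01
2.45279e+00 3.59949e+01 1.76127e-01 3.50213e-01 3.65212e+01
2.61512e+00 2.94588e+01 1.76017e-01 3.32253e-01 2.99671e+01
2.78821e+00 2.40953e+01 1.75900e-01 3.14932e-01 2.45861e+01
2.97275e+00 1.96966e+01 1.75775e-01 2.98340e-01 2.01707e+01
3.16950e+00 1.60637e+01 1.75642e-01 2.82539e-01 1.65218e+01
3.37928e+00 1.30923e+01 1.75501e-01 2.67566e-01 1.35354e+01
3.60294e+00 1.06670e+01 1.75351e-01 2.53429e-01 1.10958e+01
3.84140e+00 8.68793e+00 1.75191e-01 2.40109e-01 9.10323e+00
4.09564e+00 7.07299e+00 1.75021e-01 2.27564e-01 7.47557e+00
4.36672e+00 5.75637e+00 1.74840e-01 2.15731e-01 6.14694e+00
4.65573e+00 4.68332e+00 1.74648e-01 2.04533e-01 5.06250e+00
4.96387e+00 3.80906e+00 1.74443e-01 1.93888e-01 4.17739e+00
5.29241e+00 3.09699e+00 1.74226e-01 1.83712e-01 3.45493e+00
5.64269e+00 2.51722e+00 1.73996e-01 1.73932e-01 2.86515e+00
6.01616e+00 2.04533e+00 1.73750e-01 1.64481e-01 2.38356e+00
6.41434e+00 1.66136e+00 1.73490e-01 1.55308e-01 1.99015e+00
6.83888e+00 1.34903e+00 1.73214e-01 1.46370e-01 1.66861e+00
7.29151e+00 1.09506e+00 1.72920e-01 1.37642e-01 1.40563e+00
7.77410e+00 8.88620e-01 1.72609e-01 1.29106e-01 1.19033e+00
8.28864e+00 7.20862e-01 1.72278e-01 1.20758e-01 1.01390e+00
8.83723e+00 5.84584e-01 1.71927e-01 1.12604e-01 8.69115e-01
9.42212e+00 4.73376e-01 1.71556e-01 1.04659e-01 7.49591e-01
1.00457e+01 3.83203e-01 1.71162e-01 9.69455e-02 6.51310e-01
1.07106e+01 3.10154e-01 1.70744e-01 8.94935e-02 5.70392e-01
1.14195e+01 2.50989e-01 1.70302e-01 8.23341e-02 5.03625e-01
1.21753e+01 2.03076e-01 1.69834e-01 7.54990e-02 4.48409e-01
1.29811e+01 1.64282e-01 1.69339e-01 6.90167e-02 4.02638e-01
1.38403e+01 1.32877e-01 1.68815e-01 6.29100e-02 3.64602e-01
1.47563e+01 1.07458e-01 1.68261e-01 5.71941e-02 3.32913e-01
1.57330e+01 8.68865e-02 1.67676e-01 5.18756e-02 3.06438e-01
1.67743e+01 7.02417e-02 1.67058e-01 4.69531e-02 2.84253e-01
1.78845e+01 5.67760e-02 1.66406e-01 4.24176e-02 2.65599e-01
1.90682e+01 4.58842e-02 1.65717e-01 3.82545e-02 2.49856e-01
2.03302e+01 3.70757e-02 1.64992e-01 3.44453e-02 2.36513e-01
2.16758e+01 2.99531e-02 1.64228e-01 3.09695e-02 2.25151e-01
2.31104e+01 2.41949e-02 1.63424e-01 2.78056e-02 2.15424e-01
2.46400e+01 1.95404e-02 1.62578e-01 2.49320e-02 2.07050e-01
2.62708e+01 1.57787e-02 1.61689e-01 2.23279e-02 1.99795e-01
2.80096e+01 1.27251e-02 1.60755e-01 1.99728e-02 1.93453e-01
2.98634e+01 1.02598e-02 1.59775e-01 1.78465e-02 1.87881e-01
3.18400e+01 8.27345e-03 1.58748e-01 1.59295e-02 1.82951e-01
3.39473e+01 6.67267e-03 1.57673e-01 1.42035e-02 1.78549e-01
3.61941e+01 5.38244e-03 1.56547e-01 1.26515e-02 1.74581e-01
3.85897e+01 4.34236e-03 1.55371e-01 1.12579e-02 1.70972e-01
4.11437e+01 3.50379e-03 1.54144e-01 1.00083e-02 1.67656e-01
4.38669e+01 2.82760e-03 1.52864e-01 8.88919e-03 1.64581e-01
4.67702e+01 2.28226e-03 1.51531e-01 7.88844e-03 1.61701e-01
4.98657e+01 1.84237e-03 1.50144e-01 6.99468e-03 1.58981e-01
5.31661e+01 1.48750e-03 1.48703e-01 6.19749e-03 1.56388e-01
5.66850e+01 1.20116e-03 1.47209e-01 5.48732e-03 1.53897e-01
6.04367e+01 9.70096e-04 1.45660e-01 4.85538e-03 1.51486e-01
6.44367e+01 7.83599e-04 1.44058e-01 4.29367e-03 1.49136e-01
6.87015e+01 6.33052e-04 1.42403e-01 3.79489e-03 1.46831e-01
7.32486e+01 5.11506e-04 1.40696e-01 3.35240e-03 1.44560e-01
7.80966e+01 4.13361e-04 1.38938e-01 2.96017e-03 1.42312e-01
8.32654e+01 3.34098e-04 1.37130e-01 2.61279e-03 1.40077e-01
8.87764e+01 2.70076e-04 1.35275e-01 2.30532e-03 1.37850e-01
9.46521e+01 2.18355e-04 1.33373e-01 2.03337e-03 1.35624e-01
1.00917e+02 1.76566e-04 1.31427e-01 1.79298e-03 1.33396e-01
1.07596e+02 1.42796e-04 1.29439e-01 1.58059e-03 1.31162e-01
1.14717e+02 1.15503e-04 1.27412e-01 1.39302e-03 1.28920e-01
1.22310e+02 9.34408e-05 1.25348e-01 1.22746e-03 1.26669e-01
1.30405e+02 7.56041e-05 1.23252e-01 1.08137e-03 1.24409e-01
1.39036e+02 6.11816e-05 1.21125e-01 9.52508e-04 1.22138e-01
1.48238e+02 4.95179e-05 1.18971e-01 8.38877e-04 1.19859e-01
1.58049e+02 4.00839e-05 1.16793e-01 7.38703e-04 1.17572e-01
1.68510e+02 3.24522e-05 1.14595e-01 6.50416e-04 1.15278e-01
1.79663e+02 2.62775e-05 1.12381e-01 5.72620e-04 1.12980e-01
1.91554e+02 2.12809e-05 1.10154e-01 5.04082e-04 1.10679e-01
2.04232e+02 1.72371e-05 1.07916e-01 4.43712e-04 1.08377e-01
2.17749e+02 1.39637e-05 1.05673e-01 3.90542e-04 1.06078e-01
2.32161e+02 1.13138e-05 1.03427e-01 3.43722e-04 1.03782e-01
2.47527e+02 9.16806e-06 1.01181e-01 3.02498e-04 1.01492e-01
2.63910e+02 7.43044e-06 9.89378e-02 2.66204e-04 9.92114e-02
2.81377e+02 6.02306e-06 9.67011e-02 2.34254e-04 9.69414e-02
3.00000e+02 4.88299e-06 9.44734e-02 2.06131e-04 9.46844e-02
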