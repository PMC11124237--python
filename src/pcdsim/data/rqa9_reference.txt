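# spectral fluence rate
# columns: energy_keV fluence_rate_per_mm2_s
1.000000e+00 0.000000e+00
2.000000e+00 0.000000e+00
3.000000e+00 0.000000e+00
4.000000e+00 0.000000e+00
5.000000e+00 0.000000e+00
6.000000e+00 0.000000e+00
7.000000e+00 0.000000e+00
8.000000e+00 1.383472e-234
9.000000e+00 2.349740e-176
1.000000e+01 1.138369e-129
1.100000e+01 3.686953e-99
1.200000e+01 1.623606e-77
1.300000e+01 1.222437e-61
1.400000e+01 8.679134e-50
1.500000e+01 7.489377e-41
1.600000e+01 5.457329e-34
1.700000e+01 1.239493e-28
1.800000e+01 2.157737e-24
1.900000e+01 5.419189e-21
2.000000e+01 3.075188e-18
2.100000e+01 5.542148e-16
2.200000e+01 4.071197e-14
2.300000e+01 1.464713e-12
2.400000e+01 2.940801e-11
2.500000e+01 3.744604e-10
2.600000e+01 3.268878e-09
2.700000e+01 2.087841e-08
2.800000e+01 1.041657e-07
2.900000e+01 4.135199e-07
3.000000e+01 1.385581e-06
3.100000e+01 3.944367e-06
3.200000e+01 9.949730e-06
3.300000e+01 2.225477e-05
3.400000e+01 4.572059e-05
3.500000e+01 8.552648e-05
3.600000e+01 1.505362e-04
3.700000e+01 2.470877e-04
3.800000e+01 3.862019e-04
3.900000e+01 5.758155e-04
4.000000e+01 8.211623e-04
4.100000e+01 1.136646e-03
4.200000e+01 1.511505e-03
4.300000e+01 1.960817e-03
4.400000e+01 2.487887e-03
4.500000e+01 3.064122e-03
4.600000e+01 3.715990e-03
4.700000e+01 4.431079e-03
4.800000e+01 5.171525e-03
4.900000e+01 5.970641e-03
5.000000e+01 6.815283e-03
5.100000e+01 7.643725e-03
5.200000e+01 8.506850e-03
5.300000e+01 9.399648e-03
5.400000e+01 1.024488e-02
5.500000e+01 1.108767e-02
5.600000e+01 1.193706e-02
5.700000e+01 1.275960e-02
5.800000e+01 3.632412e-02
5.900000e+01 5.702729e-02
6.000000e+01 1.498600e-02
6.100000e+01 1.564563e-02
6.200000e+01 1.624325e-02
6.300000e+01 1.681688e-02
6.400000e+01 1.736473e-02
6.500000e+01 1.783607e-02
6.600000e+01 1.824079e-02
6.700000e+01 4.226440e-02
6.800000e+01 1.896146e-02
6.900000e+01 2.636726e-02
7.000000e+01 1.680055e-02
7.100000e+01 1.703989e-02
7.200000e+01 1.725140e-02
7.300000e+01 1.743489e-02
7.400000e+01 1.755060e-02
7.500000e+01 1.762630e-02
7.600000e+01 1.767549e-02
7.700000e+01 1.769840e-02
7.800000e+01 1.769533e-02
7.900000e+01 1.762526e-02
8.000000e+01 1.752745e-02
8.100000e+01 1.740687e-02
8.200000e+01 1.726401e-02
8.300000e+01 1.709934e-02
8.400000e+01 1.688778e-02
8.500000e+01 1.664793e-02
8.600000e+01 1.638984e-02
8.700000e+01 1.611401e-02
8.800000e+01 1.582097e-02
8.900000e+01 1.550560e-02
9.000000e+01 1.515560e-02
9.100000e+01 1.479170e-02
9.200000e+01 1.441437e-02
9.300000e+01 1.402409e-02
9.400000e+01 1.362130e-02
9.500000e+01 1.320052e-02
9.600000e+01 1.275805e-02
9.700000e+01 1.230592e-02
9.800000e+01 1.184453e-02
9.900000e+01 1.137424e-02
1.000000e+02 1.089544e-02
1.010000e+02 1.040759e-02
1.020000e+02 9.902898e-03
1.030000e+02 9.391956e-03
1.040000e+02 8.875060e-03
1.050000e+02 8.352497e-03
1.060000e+02 7.824543e-03
1.070000e+02 7.291464e-03
1.080000e+02 6.751373e-03
1.090000e+02 6.204174e-03
1.100000e+02 5.653537e-03
1.110000e+02 5.099670e-03
1.120000e+02 4.542772e-03
1.130000e+02 3.983036e-03
1.140000e+02 3.420646e-03
1.150000e+02 2.855286e-03
1.160000e+02 2.286832e-03
1.170000e+02 1.716941e-03
1.180000e+02 1.145750e-03
1.190000e+02 5.733943e-04
1.200000e+02 0.000000e+00
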