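# mass attenuation coefficients for Ce (Z=58, A=140.1160)
# photoelectric: Cromer-Liberman f'' (gemmi 0.7.4); incoherent: Klein-Nishina free-electron; coherent: Thomson x IT92 form factor
# K-edge: 40.443 keV
# columns: energy_keV photoelectric incoherent coherent total  [cm^2/g]
1.00000e+00 9.79174e+03 1.65188e-01 8.99248e+00 9.80090e+03
1.06619e+00 8.43942e+03 1.65146e-01 8.92371e+00 8.44851e+03
1.13675e+00 7.25587e+03 1.65100e-01 8.84906e+00 7.26488e+03
1.21199e+00 7.22753e+03 1.65052e-01 8.76835e+00 7.23646e+03
1.29220e+00 6.61976e+03 1.65001e-01 8.68145e+00 6.62861e+03
1.37773e+00 5.71231e+03 1.64946e-01 8.58826e+00 5.72106e+03
1.46892e+00 5.17826e+03 1.64888e-01 8.48871e+00 5.18692e+03
1.56614e+00 4.48316e+03 1.64825e-01 8.38274e+00 4.49171e+03
1.66979e+00 3.87476e+03 1.64759e-01 8.27029e+00 3.88319e+03
1.78031e+00 3.34339e+03 1.64689e-01 8.15131e+00 3.35170e+03
1.89814e+00 2.88085e+03 1.64614e-01 8.02568e+00 2.88904e+03
2.02377e+00 2.47875e+03 1.64534e-01 7.89327e+00 2.48681e+03
2.15771e+00 2.12979e+03 1.64449e-01 7.75391e+00 2.13770e+03
2.30052e+00 1.82753e+03 1.64358e-01 7.60739e+00 1.83530e+03
2.45279e+00 1.56599e+03 1.64262e-01 7.45354e+00 1.57361e+03
2.61512e+00 1.34009e+03 1.64159e-01 7.29221e+00 1.34754e+03
2.78821e+00 1.14544e+03 1.64050e-01 7.12336e+00 1.15272e+03
2.97275e+00 9.78018e+02 1.63933e-01 6.94709e+00 9.85129e+02
3.16950e+00 8.33566e+02 1.63809e-01 6.76369e+00 8.40493e+02
3.37928e+00 7.09841e+02 1.63678e-01 6.57362e+00 7.16579e+02
3.60294e+00 6.04026e+02 1.63538e-01 6.37753e+00 6.10567e+02
3.84140e+00 5.13457e+02 1.63388e-01 6.17624e+00 5.19797e+02
4.09564e+00 4.36204e+02 1.63230e-01 5.97065e+00 4.42338e+02
4.36672e+00 3.70350e+02 1.63061e-01 5.76174e+00 3.76275e+02
4.65573e+00 3.14250e+02 1.62882e-01 5.55045e+00 3.19963e+02
4.96387e+00 2.66489e+02 1.62691e-01 5.33765e+00 2.71989e+02
5.29241e+00 2.25810e+02 1.62489e-01 5.12412e+00 2.31097e+02
5.64269e+00 1.91180e+02 1.62274e-01 4.91045e+00 1.96252e+02
6.01616e+00 4.82187e+02 1.62045e-01 4.69714e+00 4.87046e+02
6.41434e+00 5.59286e+02 1.61802e-01 4.48457e+00 5.63933e+02
6.83888e+00 5.47570e+02 1.61544e-01 4.27308e+00 5.52004e+02
7.29151e+00 4.64786e+02 1.61271e-01 4.06306e+00 4.69010e+02
7.77410e+00 3.94016e+02 1.60980e-01 3.85498e+00 3.98032e+02
8.28864e+00 3.33670e+02 1.60672e-01 3.64949e+00 3.37480e+02
8.83723e+00 2.82310e+02 1.60345e-01 3.44735e+00 2.85918e+02
9.42212e+00 2.38486e+02 1.59998e-01 3.24948e+00 2.41895e+02
1.00457e+01 2.01311e+02 1.59631e-01 3.05683e+00 2.04528e+02
1.07106e+01 1.69819e+02 1.59242e-01 2.87033e+00 1.72849e+02
1.14195e+01 1.43160e+02 1.58829e-01 2.69082e+00 1.46010e+02
1.21753e+01 1.20568e+02 1.58393e-01 2.51893e+00 1.23246e+02
1.29811e+01 1.01441e+02 1.57931e-01 2.35509e+00 1.03954e+02
1.38403e+01 8.52800e+01 1.57442e-01 2.19944e+00 8.76368e+01
1.47563e+01 7.16594e+01 1.56926e-01 2.05188e+00 7.38682e+01
1.57330e+01 6.01877e+01 1.56380e-01 1.91211e+00 6.22561e+01
1.67743e+01 5.05300e+01 1.55804e-01 1.77963e+00 5.24654e+01
1.78845e+01 4.24028e+01 1.55195e-01 1.65388e+00 4.42118e+01
1.90682e+01 3.55670e+01 1.54553e-01 1.53428e+00 3.72558e+01
2.03302e+01 2.98199e+01 1.53877e-01 1.42032e+00 3.13941e+01
2.16758e+01 2.49900e+01 1.53164e-01 1.31162e+00 2.64548e+01
2.31104e+01 2.09328e+01 1.52414e-01 1.20794e+00 2.22932e+01
2.46400e+01 1.75261e+01 1.51625e-01 1.10917e+00 1.87869e+01
2.62708e+01 1.46667e+01 1.50796e-01 1.01228e+00 1.58297e+01
2.80096e+01 1.22585e+01 1.49925e-01 9.16960e-01 1.33254e+01
2.98634e+01 1.02339e+01 1.49011e-01 8.27266e-01 1.12102e+01
3.18400e+01 8.54110e+00 1.48054e-01 7.44743e-01 9.43390e+00
3.39473e+01 7.12744e+00 1.47050e-01 6.69660e-01 7.94415e+00
3.61941e+01 5.94694e+00 1.46001e-01 6.01692e-01 6.69463e+00
3.85897e+01 4.96118e+00 1.44904e-01 5.40281e-01 5.64637e+00
4.04026e+01 4.35670e+00 1.44089e-01 4.99980e-01 5.00077e+00
4.04834e+01 2.55413e+01 1.44053e-01 4.98290e-01 2.61837e+01
4.11437e+01 2.45061e+01 1.43760e-01 4.84816e-01 2.51347e+01
4.38669e+01 2.07454e+01 1.42566e-01 4.34715e-01 2.13227e+01
4.67702e+01 1.75204e+01 1.41322e-01 3.89453e-01 1.80512e+01
4.98657e+01 1.47832e+01 1.40029e-01 3.48566e-01 1.52718e+01
5.31661e+01 1.24617e+01 1.38685e-01 3.11648e-01 1.29121e+01
5.66850e+01 1.04940e+01 1.37292e-01 2.78338e-01 1.09096e+01
6.04367e+01 8.82908e+00 1.35847e-01 2.48315e-01 9.21324e+00
6.44367e+01 7.42162e+00 1.34353e-01 2.21289e-01 7.77726e+00
6.87015e+01 6.23287e+00 1.32810e-01 1.96993e-01 6.56267e+00
7.32486e+01 5.22975e+00 1.31218e-01 1.75185e-01 5.53615e+00
7.80966e+01 4.38405e+00 1.29578e-01 1.55638e-01 4.66927e+00
8.32654e+01 3.66552e+00 1.27892e-01 1.38146e-01 3.93156e+00
8.87764e+01 3.05779e+00 1.26161e-01 1.22513e-01 3.30646e+00
9.46521e+01 2.55090e+00 1.24388e-01 1.08564e-01 2.78385e+00
1.00917e+02 2.12809e+00 1.22573e-01 9.61315e-02 2.34680e+00
1.07596e+02 1.77541e+00 1.20719e-01 8.50658e-02 1.98120e+00
1.14717e+02 1.48122e+00 1.18828e-01 7.52276e-02 1.67528e+00
1.22310e+02 1.23580e+00 1.16904e-01 6.64901e-02 1.41920e+00
1.30405e+02 1.03107e+00 1.14948e-01 5.87377e-02 1.20476e+00
1.39036e+02 8.60278e-01 1.12965e-01 5.18655e-02 1.02511e+00
1.48238e+02 7.17790e-01 1.10956e-01 4.57784e-02 8.74524e-01
1.58049e+02 5.98914e-01 1.08925e-01 4.03909e-02 7.48230e-01
1.68510e+02 4.99736e-01 1.06875e-01 3.56256e-02 6.42237e-01
1.79663e+02 4.16989e-01 1.04810e-01 3.14132e-02 5.53213e-01
1.91554e+02 3.47951e-01 1.02733e-01 2.76915e-02 4.78375e-01
2.04232e+02 2.90349e-01 1.00646e-01 2.44050e-02 4.15401e-01
2.17749e+02 2.42288e-01 9.85541e-02 2.15040e-02 3.62346e-01
2.32161e+02 2.02188e-01 9.64590e-02 1.89443e-02 3.17591e-01
2.47527e+02 1.68728e-01 9.43642e-02 1.66865e-02 2.79778e-01
2.63910e+02 1.40809e-01 9.22725e-02 1.46956e-02 2.47777e-01
2.81377e+02 1.17513e-01 9.01866e-02 1.29405e-02 2.20640e-01
3.00000e+02 9.80739e-02 8.81089e-02 1.13938e-02 1.97577e-01
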