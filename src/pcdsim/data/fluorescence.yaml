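# K-shell fluorescence data: K-edge energy (keV), K fluorescence yield
# omega_K, and the principal K emission lines as (energy keV, relative
# intensity).  Line energies and intensities are standard X-ray data-booklet
# values; Kbeta entries merge Kbeta1/Kbeta3 (and Kbeta2 where relevant) into
# a single weighted line.  Intensities are relative (normalized on load).
Cu:
  k_edge_keV: 8.979
  omega_k: 0.441
  lines:
    - [8.048, 100.0]   # Kalpha1
    - [8.028, 51.0]    # Kalpha2
    - [8.905, 17.0]    # Kbeta
Zn:
  k_edge_keV: 9.659
  omega_k: 0.474
  lines:
    - [8.639, 100.0]
    - [8.616, 51.0]
    - [9.572, 17.0]
Br:
  k_edge_keV: 13.474
  omega_k: 0.618
  lines:
    - [11.924, 100.0]
    - [11.878, 52.0]
    - [13.291, 19.0]
Cd:
  k_edge_keV: 26.711
  omega_k: 0.843
  lines:
    - [23.174, 100.0]
    - [22.984, 53.0]
    - [26.096, 27.0]
I:
  k_edge_keV: 33.169
  omega_k: 0.884
  lines:
    - [28.612, 100.0]
    - [28.317, 54.0]
    - [32.295, 28.0]
Te:
  k_edge_keV: 31.814
  omega_k: 0.875
  lines:
    - [27.472, 100.0]
    - [27.202, 54.0]
    - [30.995, 28.0]
La:
  k_edge_keV: 38.925
  omega_k: 0.906
  lines:
    - [33.442, 100.0]
    - [33.034, 55.0]
    - [37.801, 30.0]
Ce:
  k_edge_keV: 40.443
  omega_k: 0.911
  lines:
    - [34.719, 100.0]
    - [34.279, 55.0]
    - [39.257, 30.0]
W:
  k_edge_keV: 69.525
  omega_k: 0.958
  lines:
    - [59.318, 100.0]
    - [57.982, 58.0]
    - [67.244, 33.0]
    - [69.067, 9.0]
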