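# Built-in materials registry: composition as element mass fractions
# (normalized on load), bulk density in g/cm^3.
czt:
  # Cd0.9Zn0.1Te; mass fractions from the formula weights
  composition: {Cd: 0.42996, Zn: 0.02779, Te: 0.54226}
  density: 5.78
labr3_ce:
  # LaBr3 with 5% of the La sites occupied by Ce
  composition: {La: 0.34847, Ce: 0.01850, Br: 0.63303}
  density: 5.29
water:
  composition: {H: 0.11190, O: 0.88810}
  density: 1.0
aluminum:
  composition: {Al: 1.0}
  density: 2.699
copper:
  composition: {Cu: 1.0}
  density: 8.96
beryllium:
  composition: {Be: 1.0}
  density: 1.848
tungsten:
  composition: {W: 1.0}
  density: 19.3
ptfe:
  # (C2F4)n reflector material
  composition: {C: 0.24018, F: 0.75982}
  density: 2.2
iodine_water_lesion:
  # aqueous iodine solution; fractions as specified sum to 1.0001 and are
  # normalized on load
  composition: {I: 0.2308, O: 0.6832, H: 0.0861}
  density: 1.3
air:
  composition: {N: 0.755, O: 0.232, Ar: 0.013}
  density: 0.0012
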