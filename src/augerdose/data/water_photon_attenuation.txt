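# Mass attenuation coefficient of liquid water for photons, 0.5 - 10 keV.
# Columns: photon energy (keV), mu/rho (cm^2/g), total with coherent.
# Rows at and above 1 keV are standard evaluated values for liquid
# water; rows between 0.5 and 1 keV extend the above-edge branch with
# the E^-3 photoelectric power law anchored at 1 keV (the oxygen K
# edge at 0.543 keV is not resolved; this band only serves the weak
# 0.85 keV l fluorescence line, which is absorbed within microns
# either way).  Table version: 1.
0.5     3.262e+04
0.6     1.888e+04
0.7     1.189e+04
0.8     7.965e+03
0.9     5.595e+03
1.0     4.078e+03
1.5     1.376e+03
2.0     6.173e+02
3.0     1.929e+02
4.0     8.278e+01
5.0     4.258e+01
6.0     2.464e+01
8.0     1.037e+01
10.0    5.329e+00
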