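# Elemental mass attenuation coefficients (total, with coherent scatter)
# for Na, after the standard NIST/XCOM reference tabulations.
# Columns: photon energy [keV]   mu/rho [cm^2/g]
# Duplicated energy rows mark an absorption edge: the first row is the
# below-edge branch, the second the above-edge branch.
5        118
6        70.6
8        30.3
10       15.57
15       4.694
20       2.057
30       0.7197
40       0.3969
50       0.2804
60       0.2268
80       0.1796
100      0.1585
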