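# Elemental mass attenuation coefficients (total, with coherent scatter)
# for Cs, after the standard NIST/XCOM reference tabulations.
# Columns: photon energy [keV]   mu/rho [cm^2/g]
# Duplicated energy rows mark an absorption edge: the first row is the
# below-edge branch, the second the above-edge branch.
5        859
6        542
8        254
10       141
15       47.5
20       22
30       9.67
36       5.8
36       33.1
40       24.9
50       13.9
60       8.56
80       3.97
100      2.19
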