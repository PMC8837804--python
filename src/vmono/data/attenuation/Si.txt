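# Elemental mass attenuation coefficients (total, with coherent scatter)
# for Si, after the standard NIST/XCOM reference tabulations.
# Columns: photon energy [keV]   mu/rho [cm^2/g]
# Duplicated energy rows mark an absorption edge: the first row is the
# below-edge branch, the second the above-edge branch.
5        245
6        147
8        64.7
10       33.89
15       10.34
20       4.464
30       1.436
40       0.7012
50       0.4385
60       0.3207
80       0.2228
100      0.1835
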