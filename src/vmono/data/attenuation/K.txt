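# Elemental mass attenuation coefficients (total, with coherent scatter)
# for K, after the standard NIST/XCOM reference tabulations.
# Columns: photon energy [keV]   mu/rho [cm^2/g]
# Duplicated energy rows mark an absorption edge: the first row is the
# below-edge branch, the second the above-edge branch.
5        630
6        371
8        159
10       83
15       25.6
20       11
30       3.38
40       1.5
50       0.821
60       0.529
80       0.312
100      0.229
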