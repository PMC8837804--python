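# Elemental mass attenuation coefficients (total, with coherent scatter)
# for S, after the standard NIST/XCOM reference tabulations.
# Columns: photon energy [keV]   mu/rho [cm^2/g]
# Duplicated energy rows mark an absorption edge: the first row is the
# below-edge branch, the second the above-edge branch.
5        395
6        231
8        99
10       50.5
15       15.3
20       6.708
30       2.113
40       0.96
50       0.56
60       0.41
80       0.259
100      0.202
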