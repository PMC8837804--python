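# Elemental mass attenuation coefficients (total, with coherent scatter)
# for P, after the standard NIST/XCOM reference tabulations.
# Columns: photon energy [keV]   mu/rho [cm^2/g]
# Duplicated energy rows mark an absorption edge: the first row is the
# below-edge branch, the second the above-edge branch.
5        349
6        202
8        84
10       42
15       12.5
20       5.358
30       1.7
40       0.793
50       0.478
60       0.336
80       0.245
100      0.197
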