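# Elemental mass attenuation coefficients (total, with coherent scatter)
# for O, after the standard NIST/XCOM reference tabulations.
# Columns: photon energy [keV]   mu/rho [cm^2/g]
# Duplicated energy rows mark an absorption edge: the first row is the
# below-edge branch, the second the above-edge branch.
5        47
6        27.9
8        11.63
10       5.952
15       1.836
20       0.8651
30       0.3779
40       0.2585
50       0.2132
60       0.1907
80       0.1678
100      0.1551
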