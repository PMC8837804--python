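# Elemental mass attenuation coefficients (total, with coherent scatter)
# for Be, after the standard NIST/XCOM reference tabulations.
# Columns: photon energy [keV]   mu/rho [cm^2/g]
# Duplicated energy rows mark an absorption edge: the first row is the
# below-edge branch, the second the above-edge branch.
5        4.369
6        2.527
8        1.124
10       0.6466
15       0.307
20       0.2251
30       0.1792
40       0.164
50       0.1554
60       0.1493
80       0.1401
100      0.1328
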