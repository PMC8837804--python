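# Elemental mass attenuation coefficients (total, with coherent scatter)
# for C, after the standard NIST/XCOM reference tabulations.
# Columns: photon energy [keV]   mu/rho [cm^2/g]
# Duplicated energy rows mark an absorption edge: the first row is the
# below-edge branch, the second the above-edge branch.
5        18.85
6        10.74
8        4.576
10       2.373
15       0.8071
20       0.442
30       0.2562
40       0.2076
50       0.1871
60       0.1753
80       0.161
100      0.1514
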