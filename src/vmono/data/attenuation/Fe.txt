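# Elemental mass attenuation coefficients (total, with coherent scatter)
# for Fe, after the standard NIST/XCOM reference tabulations.
# Columns: photon energy [keV]   mu/rho [cm^2/g]
# Duplicated energy rows mark an absorption edge: the first row is the
# below-edge branch, the second the above-edge branch.
5        152
6        87.9
7.112    53
7.112    433
8        305.8
10       170.6
15       57.08
20       25.68
30       8.176
40       3.629
50       1.958
60       1.205
80       0.5952
100      0.3717
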