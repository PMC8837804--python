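# Elemental mass attenuation coefficients (total, with coherent scatter)
# for Cl, after the standard NIST/XCOM reference tabulations.
# Columns: photon energy [keV]   mu/rho [cm^2/g]
# Duplicated energy rows mark an absorption edge: the first row is the
# below-edge branch, the second the above-edge branch.
5        450
6        263
8        113
10       59
15       18.19
20       7.739
30       2.339
40       1.09
50       0.627
60       0.421
80       0.27
100      0.207
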