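# Elemental mass attenuation coefficients (total, with coherent scatter)
# for Mg, after the standard NIST/XCOM reference tabulations.
# Columns: photon energy [keV]   mu/rho [cm^2/g]
# Duplicated energy rows mark an absorption edge: the first row is the
# below-edge branch, the second the above-edge branch.
5        155
6        91
8        39.5
10       20.8
15       6.358
20       2.763
30       0.9417
40       0.468
50       0.308
60       0.25
80       0.184
100      0.158
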