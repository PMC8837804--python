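# Elemental mass attenuation coefficients (total, with coherent scatter)
# for I, after the standard NIST/XCOM reference tabulations.
# Columns: photon energy [keV]   mu/rho [cm^2/g]
# Duplicated energy rows mark an absorption edge: the first row is the
# below-edge branch, the second the above-edge branch.
5        771
6        488
8        231
10       126
15       42.3
20       19.5
30       8.561
33.2     6.42
33.2     36.6
40       22.1
50       12.32
60       7.579
80       3.51
100      1.942
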