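# Elemental mass attenuation coefficients (total, with coherent scatter)
# for N, after the standard NIST/XCOM reference tabulations.
# Columns: photon energy [keV]   mu/rho [cm^2/g]
# Duplicated energy rows mark an absorption edge: the first row is the
# below-edge branch, the second the above-edge branch.
5        31.4
6        17.9
8        7.562
10       3.879
15       1.236
20       0.6178
30       0.3066
40       0.2288
50       0.198
60       0.1817
80       0.1639
100      0.1529
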