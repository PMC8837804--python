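# Elemental mass attenuation coefficients (total, with coherent scatter)
# for Ca, after the standard NIST/XCOM reference tabulations.
# Columns: photon energy [keV]   mu/rho [cm^2/g]
# Duplicated energy rows mark an absorption edge: the first row is the
# below-edge branch, the second the above-edge branch.
5        760
6        470
8        198
10       102
15       30.5
20       13.06
30       4.08
40       1.83
50       0.9912
60       0.6351
80       0.3656
100      0.2451
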