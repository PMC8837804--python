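# Elemental mass attenuation coefficients (total, with coherent scatter)
# for H, after the standard NIST/XCOM reference tabulations.
# Columns: photon energy [keV]   mu/rho [cm^2/g]
# Duplicated energy rows mark an absorption edge: the first row is the
# below-edge branch, the second the above-edge branch.
5        0.4193
6        0.4042
8        0.3914
10       0.3854
15       0.3764
20       0.3695
30       0.357
40       0.3458
50       0.3355
60       0.326
80       0.3091
100      0.2944
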