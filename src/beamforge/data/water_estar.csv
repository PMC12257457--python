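# Electron total (collision + radiative) mass stopping power for liquid
# water, MeV cm^2/g. CSDA ranges are obtained by numerically integrating
# 1/S over energy, so range and stopping power are mutually consistent.
energy_mev,stopping_power
0.010,22.56
0.015,16.47
0.020,13.17
0.030,9.653
0.040,7.788
0.050,6.614
0.060,5.809
0.080,4.769
0.100,4.126
0.150,3.250
0.200,2.807
0.300,2.371
0.400,2.166
0.500,2.054
0.600,1.985
0.800,1.912
1.000,1.862
1.250,1.844
1.500,1.841
2.000,1.850
3.000,1.889
4.000,1.934
5.000,1.979
6.000,2.026
8.000,2.113
10.000,2.197
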