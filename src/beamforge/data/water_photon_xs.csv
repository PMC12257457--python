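# Photon interaction data for liquid water (cm^2/g).
# mu_pe: photoelectric mass attenuation; mu_pair: pair+triplet production.
# Incoherent (Compton) attenuation is computed from the Klein-Nishina cross
# section at runtime so that attenuation and angular sampling stay consistent.
# Coherent scattering is neglected.
energy_mev,mu_pe,mu_pair
0.010,5.10e+00,0.0
0.015,1.47e+00,0.0
0.020,6.17e-01,0.0
0.030,1.85e-01,0.0
0.040,7.53e-02,0.0
0.050,3.70e-02,0.0
0.060,2.05e-02,0.0
0.080,7.94e-03,0.0
0.100,3.86e-03,0.0
0.150,1.07e-03,0.0
0.200,4.27e-04,0.0
0.300,1.17e-04,0.0
0.400,4.80e-05,0.0
0.500,2.40e-05,0.0
0.600,1.40e-05,0.0
0.800,6.00e-06,0.0
1.000,3.00e-06,0.0
1.022,2.90e-06,0.0
1.250,2.00e-06,1.8e-05
1.500,1.50e-06,7.6e-05
2.000,1.00e-06,3.91e-04
3.000,5.00e-07,1.13e-03
4.000,3.00e-07,1.87e-03
5.000,2.00e-07,2.55e-03
6.000,1.50e-07,3.16e-03
8.000,1.00e-07,4.21e-03
10.000,8.00e-08,5.07e-03
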