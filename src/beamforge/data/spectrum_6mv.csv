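# Generic 6 MV photon energy spectrum (bin centers)
energy_mev,weight
0.20,0.07921257
0.60,0.15236865
1.00,0.16282631
1.40,0.14616145
1.80,0.12049182
2.20,0.09442521
2.60,0.07155152
3.00,0.05293550
3.40,0.03846670
3.80,0.02756575
4.20,0.01953510
4.60,0.01371843
5.00,0.00956086
5.40,0.00662065
5.80,0.00455948
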