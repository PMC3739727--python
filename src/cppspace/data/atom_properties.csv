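element,mass,sanderson_en,polarizability,vdw_volume
H,1.008,2.592,0.667,6.709
C,12.011,2.746,1.760,22.449
N,14.007,3.194,1.100,15.599
O,15.999,3.654,0.802,11.494
S,32.066,2.957,2.900,24.429
P,30.974,2.515,3.630,26.522
F,18.998,4.000,0.557,9.203
Cl,35.453,3.475,2.180,23.453
Br,79.904,3.219,3.050,31.059
I,126.904,2.778,5.350,38.792
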