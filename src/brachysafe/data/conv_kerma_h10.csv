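# kind=kerma_to_h10 units=Sv_per_Gy
energy_keV,coefficient
10,0.008
15,0.26
20,0.61
30,1.1
40,1.47
50,1.67
60,1.74
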