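# kind=fluence_to_h10 units=pSv_cm2
energy_keV,coefficient
10,0.061
15,0.83
20,1.05
30,0.81
40,0.64
50,0.55
60,0.51
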