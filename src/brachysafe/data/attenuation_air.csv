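# material=air density_g_cm3=0.001205
energy_keV,mu_total_per_cm,mu_photoelectric_per_cm,mu_incoherent_per_cm,mu_coherent_per_cm
5,4.852535e-02,4.780697e-02,2.363767e-04,4.820000e-04
6,2.820905e-02,2.759119e-02,2.354842e-04,3.823727e-04
8,1.195480e-02,1.145573e-02,2.337254e-04,2.653473e-04
10,6.169600e-03,5.737733e-03,2.320008e-04,1.998660e-04
15,1.944870e-03,1.597611e-03,2.278322e-04,1.194271e-04
20,9.373695e-04,6.306365e-04,2.238566e-04,8.287639e-05
30,4.263290e-04,1.603741e-04,2.164333e-04,4.952163e-05
40,2.994425e-04,5.543768e-05,2.096393e-04,3.436551e-05
50,2.506400e-04,2.135751e-05,2.033976e-04,2.588493e-05
60,2.259375e-04,7.760177e-06,1.976427e-04,2.053463e-05
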