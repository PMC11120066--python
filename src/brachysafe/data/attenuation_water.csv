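# material=water density_g_cm3=0.998
energy_keV,mu_total_per_cm,mu_photoelectric_per_cm,mu_incoherent_per_cm,mu_coherent_per_cm
5,4.249484e+01,4.185798e+01,2.176983e-01,4.191600e-01
6,2.459072e+01,2.404132e+01,2.168763e-01,3.325214e-01
8,1.034926e+01,9.903250e+00,2.152566e-01,2.307531e-01
10,5.318342e+00,4.930865e+00,2.136682e-01,1.738088e-01
15,1.669654e+00,1.355968e+00,2.098291e-01,1.038570e-01
20,8.079808e-01,5.297417e-01,2.061676e-01,7.207151e-02
30,3.748488e-01,1.324526e-01,1.993309e-01,4.306533e-02
40,2.677634e-01,4.480451e-02,1.930737e-01,2.988516e-02
50,2.264462e-01,1.661078e-02,1.873252e-01,2.251022e-02
60,2.054882e-01,5.605662e-03,1.820251e-01,1.785746e-02
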