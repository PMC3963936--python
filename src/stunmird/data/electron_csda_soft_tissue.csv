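# Electron collision stopping power and CSDA range in soft tissue
# (water-equivalent values, ESTAR-style tabulation; density is applied separately).
# Log-log interpolation is intended between grid points.
energy_keV,stopping_power_MeV_cm2_g,csda_range_g_cm2
0.1,230.0,4.0e-07
0.2,212.0,8.5e-07
0.5,172.0,2.1e-06
1,126.0,4.60e-06
2,77.5,1.54e-05
3,57.4,3.05e-05
4,46.3,4.98e-05
5,39.0,7.32e-05
6,33.9,1.002e-04
8,27.1,1.670e-04
10,22.6,2.515e-04
15,16.6,5.147e-04
20,13.2,8.566e-04
30,9.65,1.756e-03
40,7.78,2.919e-03
50,6.60,4.320e-03
60,5.80,5.940e-03
80,4.76,9.773e-03
100,4.12,1.431e-02
125,3.59,2.074e-02
150,3.24,2.817e-02
200,2.79,4.506e-02
300,2.36,8.426e-02
400,2.15,1.258e-01
500,2.03,1.704e-01
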