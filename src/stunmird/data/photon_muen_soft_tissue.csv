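# Photon mass energy-absorption coefficients mu_en/rho for soft tissue
# (water-equivalent values, XCOM/NIST-style tabulation).
# Log-log interpolation is intended between grid points.
energy_keV,muen_rho_cm2_g
1,4065
1.5,1372
2,615.3
3,191.7
4,81.70
5,41.88
6,24.05
8,9.915
10,4.944
15,1.374
20,0.5503
30,0.1557
40,0.06947
50,0.04223
60,0.03190
80,0.02597
100,0.02546
150,0.02764
200,0.02967
300,0.03192
500,0.03279
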