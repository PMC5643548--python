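# Water photon mass attenuation / mass energy-absorption coefficients, cm^2/g (standard reference tabulation)
energy_keV,mu_rho,muen_rho
1,4078,4065
1.5,1376,1372
2,617.3,615.2
3,192.9,191.7
4,82.78,81.91
5,42.58,41.88
6,24.64,23.97
8,10.37,9.915
10,5.329,4.944
15,1.673,1.374
20,0.8096,0.5503
30,0.3756,0.1557
40,0.2683,0.0695
50,0.2269,0.04223
60,0.2059,0.0319
80,0.1837,0.02597
100,0.1707,0.02546
150,0.1505,0.02764
200,0.137,0.02967
300,0.1186,0.03192
400,0.1061,0.03279
500,0.0969,0.03299
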