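# Copper photon mass attenuation coefficient, cm^2/g (standard reference tabulation)
energy_keV,mu_rho
1,10570
1.5,4418
2,2154
3,748.8
4,341.7
5,189.3
6,118.9
8,52.55
8.9745,38.29
8.9835,278.4
10,215.9
15,74.05
20,33.79
30,10.92
40,4.862
50,2.613
60,1.593
80,0.763
100,0.4584
150,0.2217
200,0.1559
300,0.1119
400,0.0949
500,0.0838
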