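# Electron collision stopping power (keV/nm) and CSDA range (nm) in liquid water; range anchors from standard tabulations, stopping power = dE/dR
energy_keV,stopping_keV_per_nm,csda_range_nm
0.05,0.020625234,2.54
0.052981864,0.02067103,2.6844116
0.056141559,0.020716466,2.8370982
0.05948969,0.020761539,2.9985376
0.063037493,0.020806246,3.1692353
0.066796879,0.020850585,3.3497263
0.070780463,0.020894553,3.5405768
0.075001618,0.020938148,3.7423858
0.079474511,0.020981368,3.9557873
0.084214156,0.021024209,4.1814522
0.08923646,0.021066671,4.4200905
0.09455828,0.02110875,4.6724538
0.10019748,0.021150519,4.9393372
0.10617299,0.021193802,5.2215677
0.11250485,0.021236213,5.5200256
0.11921434,0.021277713,5.8356586
0.12632396,0.021318266,6.1694709
0.13385758,0.021357835,6.5225267
0.14184048,0.021396382,6.8959544
0.15029946,0.021433871,7.2909498
0.15926291,0.021470262,7.708781
0.16876092,0.021505521,8.1507924
0.17882537,0.021539608,8.6184096
0.18949003,0.021572488,9.1131447
0.2007907,0.021601283,9.6366036
0.21276531,0.021593833,10.19106
0.22545406,0.021592624,10.778701
0.23889953,0.021598093,11.401326
0.25314685,0.021610693,12.060807
0.26824384,0.021630897,12.759088
0.28424117,0.021659197,13.498183
0.30119254,0.021696106,14.280178
0.31915485,0.021742162,15.107227
0.33818838,0.021797929,15.981549
0.35835702,0.021863998,16.905428
0.37972846,0.021940993,17.881208
0.40237444,0.02202957,18.911288
0.42637096,0.022130425,19.998116
0.45179856,0.022244293,21.144189
0.47874261,0.022371959,22.352035
0.50729352,0.022789738,23.622237
0.53754713,0.02395904,24.91581
0.56960498,0.024937123,26.225957
0.60357468,0.025644536,27.567669
0.63957023,0.026016289,28.95951
0.67771247,0.026012469,30.423899
0.7181294,0.02562449,31.987561
0.76095669,0.024875038,33.682167
0.80633809,0.023812074,35.545254
0.8544259,0.022499258,37.62149
0.90538155,0.021005825,39.964392
0.95937605,0.01939833,42.638638
1.0165906,0.017441363,45.731215
1.0772173,0.015204797,49.465925
1.1414597,0.013489613,53.962482
1.2095332,0.012127074,59.295273
1.2816665,0.011021431,65.545152
1.3581016,0.010115041,72.795311
1.4390951,0.0093718023,81.125716
1.5249189,0.0087687834,90.605793
1.6158609,0.0082918897,101.28512
1.7122264,0.007933764,113.18206
1.814339,0.0076931183,126.27046
1.9225412,0.0075752513,140.465
2.0371964,0.0074638819,155.64801
2.1586893,0.0071361952,172.30057
2.2874276,0.0068259695,190.75237
2.4238436,0.0065325255,211.18804
2.5683951,0.0062551956,233.80882
2.7215672,0.0059933266,258.83366
2.8838741,0.0057462815,286.50023
3.0558605,0.0055131726,317.06609
3.2381037,0.005289355,350.82252
3.4312155,0.0050729858,388.11163
3.6358439,0.0048636505,429.31748
3.8526757,0.0046609788,474.86966
4.0824389,0.0044646408,525.2492
4.3259045,0.0042743437,580.99543
4.5838897,0.004089828,642.71371
4.8572604,0.0039108651,711.0844
5.1469343,0.0037373524,786.87355
5.4538835,0.0035725543,870.90619
5.7791383,0.0034171885,964.02836
6.1237904,0.0032708958,1067.154
6.4889967,0.0031333239,1181.2723
6.8759828,0.0030041286,1307.4512
7.2860478,0.0028799361,1446.8872
7.7205679,0.0027598126,1601.0565
8.1810017,0.0026444547,1771.5383
8.6688944,0.0025336431,1960.0778
9.1858838,0.0024271717,2168.6119
9.733705,0.0023248468,2399.2919
10.314197,0.0022327612,2654.3043
10.929308,0.0021463923,2935.311
11.581102,0.0020590183,3245.3837
12.271767,0.0019705674,3588.2934
13.003622,0.0018810708,3968.4533
13.779123,0.0017906528,4391.0411
14.600873,0.0016995204,4862.147
15.471629,0.0016041445,5389.3566
16.394315,0.0015157427,5981.5793
17.372027,0.0014400531,6643.9043
18.408048,0.0013764142,7380.3928
19.505854,0.0013244434,8194.1565
20.66913,0.0012775015,9088.143
21.901781,0.0012282275,10072.33
23.207944,0.0011789821,11157.902
24.592003,0.0011296524,12357.349
26.058603,0.0010801782,13685.184
27.612668,0.0010305483,15158.312
29.259413,0.00098079598,16796.482
31.004365,0.00092895946,18624.223
32.853381,0.00088165145,20669.051
34.812667,0.00084172322,22945.334
36.8888,0.00080890423,25463.504
39.088748,0.00078309532,28229.966
41.419895,0.00076309114,31246.344
43.890066,0.00073977377,34532.549
46.50755,0.00071130967,38139.164
49.281134,0.00067771138,42132.059
52.220128,0.0006456599,46580.097
55.334394,0.00061753727,51514.494
58.634388,0.00059205923,56974.72
62.131184,0.00056711965,63008.067
65.836519,0.00054294462,69688.392
69.76283,0.00052070004,77075.905
73.923296,0.00050032044,85230.624
78.331881,0.00048174656,94214.221
83.003382,0.00046360856,104098.27
87.953479,0.00044626474,114985.41
93.198786,0.00043038695,126958.78
98.756909,0.00041593351,140100.66
104.6465,0.00040111489,154518.23
110.88734,0.00038672,170368.59
117.50036,0.00037314407,187782.31
124.50776,0.00036035497,206897.6
131.93307,0.00034832195,227862.1
139.8012,0.00033701574,250833.15
148.13856,0.00032640856,275977.84
156.97314,0.0003156574,303503.27
166.33459,0.00030582297,333646.33
176.25434,0.00029717512,366565.31
186.76567,0.0002897089,402404.49
197.90387,0.00028342966,441291.04
209.70632,0.0002772637,483388.91
222.21263,0.00027096825,529019.93
235.46479,0.00026463766,578511.79
249.50727,0.00025823692,632231.97
264.38721,0.00025173679,690595.88
280.15455,0.00024511382,754074.1
296.86221,0.0002383503,823200.86
314.56626,0.00023183125,898544.86
333.32614,0.00022613699,980510.14
353.20481,0.00022127365,1069411.6
374.26899,0.00021725438,1165521.6
396.58937,0.0002141018,1269055.4
420.24089,0.00021114356,1380294.1
445.30292,0.00020827118,1499820.2
471.85957,0.00020553308,1628190.4
500,0.00020291174,1766000
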