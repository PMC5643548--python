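# Electron collision stopping power (keV/nm) and CSDA range (nm) in gold (density 19.3 g/cm^3); from the water table scaled by a gold/water mass-range ratio
energy_keV,stopping_keV_per_nm,csda_range_nm
0.05,0.16586147,0.31585492
0.052981864,0.16629012,0.33380955
0.056141559,0.16671901,0.35278594
0.05948969,0.16714778,0.37284237
0.063037493,0.16757637,0.39404048
0.066796879,0.16800475,0.41644542
0.070780463,0.16843287,0.44012609
0.075001618,0.16886069,0.46515534
0.079474511,0.16928815,0.49161019
0.084214156,0.16971523,0.51957206
0.08923646,0.17014186,0.54912708
0.09455828,0.17056802,0.58036629
0.10019748,0.17099802,0.61338598
0.10617299,0.17143456,0.6482861
0.11250485,0.17187113,0.68517304
0.11921434,0.17230283,0.7241612
0.12632396,0.17272932,0.76537176
0.13385758,0.17315025,0.80893301
0.14184048,0.17356528,0.85498084
0.15029946,0.17397406,0.90365918
0.15926291,0.17437625,0.95512049
0.16876092,0.17477149,1.0095263
0.17882537,0.17515943,1.0670476
0.18949003,0.17553932,1.1278659
0.2007907,0.1758218,1.1921735
0.21276531,0.17595523,1.2602449
0.22545406,0.17606177,1.3323432
0.23889953,0.17622497,1.4086826
0.25314685,0.17644868,1.489486
0.26824384,0.17673687,1.5749841
0.28424117,0.17709373,1.665416
0.30119254,0.17752362,1.7610285
0.31915485,0.17803111,1.8620759
0.33818838,0.17862103,1.9688201
0.35835702,0.17929842,2.0815299
0.37972846,0.18006863,2.2004803
0.40237444,0.1809373,2.3259525
0.42637096,0.18191041,2.4582328
0.45179856,0.18299431,2.597612
0.47874261,0.1843373,2.7443844
0.50729352,0.18889157,2.8986038
0.53754713,0.19732638,3.0554719
0.56960498,0.20557263,3.2141461
0.60357468,0.211593,3.3764552
0.63957023,0.21484369,3.54466
0.67771247,0.21498593,3.7214876
0.7181294,0.21193885,3.9101832
0.76095669,0.20588101,4.1145881
0.80633809,0.19720275,4.3392483
0.8544259,0.18642811,4.5895667
0.90538155,0.17413107,4.872009
0.95937605,0.16067518,5.1943818
1.0165906,0.14438295,5.5671568
1.0772173,0.12698208,6.0169413
1.1414597,0.11266705,6.5577904
1.2095332,0.10135794,7.1983066
1.2816665,0.092222693,7.9477797
1.3581016,0.084765884,8.8156753
1.4390951,0.078680491,9.8109543
1.5249189,0.073774077,10.941187
1.6158609,0.069931125,12.211436
1.7122264,0.067095149,13.622908
1.814339,0.065263612,15.171385
1.9225412,0.064405711,16.845528
2.0371964,0.063244083,18.630158
2.1586893,0.060982463,20.581696
2.2874276,0.058497165,22.738015
2.4238436,0.056144111,25.11935
2.5683951,0.053918255,27.747663
2.7215672,0.051814673,30.646742
2.8838741,0.049828442,33.842292
3.0558605,0.047945864,37.362051
3.2381037,0.046138786,41.237372
3.4312155,0.04438687,45.505188
3.6358439,0.042685412,50.206892
3.8526757,0.041031489,55.388691
4.0824389,0.039422536,61.102227
4.3259045,0.037856311,67.405291
4.5838897,0.036330875,74.362637
4.8572604,0.034844451,82.046917
5.1469343,0.03340292,90.539801
5.4538835,0.032024962,99.928798
5.7791383,0.030722399,110.30283
6.1237904,0.029493594,121.75757
6.4889967,0.028335959,134.39623
6.8759828,0.027242363,148.32983
7.2860478,0.02619089,163.6828
7.7205679,0.025169934,180.60983
8.1810017,0.02418472,199.2757
8.6688944,0.023234314,219.86214
9.1858838,0.022317207,242.57068
9.733705,0.021443065,267.62485
10.314197,0.020658417,295.2428
10.929308,0.019940111,325.54557
11.581102,0.019214504,358.83255
12.271767,0.01847146,395.47995
13.003622,0.017710834,435.92798
13.779123,0.016933468,480.6929
14.600873,0.016135049,530.3815
15.471629,0.015314389,585.75259
16.394315,0.014537461,647.69521
17.372027,0.013872769,716.67094
18.408048,0.013321865,793.02188
19.505854,0.012873703,876.98153
20.66913,0.012466024,968.76101
21.901781,0.012045254,1069.3137
23.207944,0.011615962,1179.7049
24.592003,0.011180112,1301.12
26.058603,0.010737118,1434.9374
27.612668,0.010286918,1582.764
29.259413,0.0098262086,1746.4771
31.004365,0.0093559571,1928.4209
32.853381,0.0089163471,2131.2122
34.812667,0.0085464555,2356.08
36.8888,0.0082474185,2603.8374
39.088748,0.008017985,2874.8835
41.419895,0.007828691,3169.1369
43.890066,0.0076176652,3488.3787
46.50755,0.0073495238,3837.4633
49.281134,0.0070345718,4222.7197
52.220128,0.0067233074,4650.7017
55.334394,0.0064475928,5124.1479
58.634388,0.0061950426,5646.609
62.131184,0.0059499657,6222.3969
65.836519,0.005710614,6858.4242
69.76283,0.005488413,7560.2262
73.923296,0.0052841325,8333.31
78.331881,0.0050949972,9183.3493
83.003382,0.0049120811,10116.995
87.953479,0.0047352416,11143.929
93.198786,0.0045718438,12271.954
98.756909,0.0044196627,13508.834
104.6465,0.004271583,14864.115
110.88734,0.0041270996,16350.982
117.50036,0.003990436,17981.11
124.50776,0.0038614783,19766.876
131.93307,0.0037399529,21721.477
139.8012,0.0036255989,23858.956
148.13856,0.0035162815,26194.206
156.97314,0.0034093001,28745.832
166.33459,0.0033091225,31535.154
176.25434,0.0032212625,34575.97
186.76567,0.0031458894,37880.718
197.90387,0.0030809584,41460.214
209.70632,0.0030188621,45328.725
222.21263,0.0029548764,49515.284
235.46479,0.0028899399,54049.362
249.50727,0.0028237553,58964.051
264.38721,0.0027560187,64296.806
280.15455,0.00268649,70090.111
296.86221,0.002615652,76392.242
314.56626,0.0025476422,83254.559
333.32614,0.002487324,90713.088
353.20481,0.0024359606,98795.647
374.26899,0.0023937111,107526.24
396.58937,0.0023593916,116923.74
420.24089,0.0023284258,127013.32
445.30292,0.0022980393,137848.02
471.85957,0.002268827,149478.62
500,0.0022412836,161959.59
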