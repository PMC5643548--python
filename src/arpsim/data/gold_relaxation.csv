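# Principal relaxation lines; line energy derived from bindings: fluor E=B(i)-B(f1), auger E=B(i)-B(f1)-B(f2); probs conditional on branch
initial,mode,final1,final2,prob
K,fluor,L3,,0.47
K,fluor,L2,,0.27
K,fluor,M3,,0.16
K,fluor,M2,,0.05
K,fluor,N,,0.05
K,auger,L2,L3,0.5
K,auger,L3,L3,0.25
K,auger,L1,L3,0.15
K,auger,L3,M5,0.1
L1,fluor,M3,,0.6
L1,fluor,M2,,0.4
L1,auger,L3,M5,0.5
L1,auger,L2,N,0.2
L1,auger,M2,M3,0.3
L2,fluor,M4,,0.9
L2,fluor,N,,0.1
L2,auger,M4,M5,0.5
L2,auger,M4,N,0.3
L2,auger,L3,N,0.2
L3,fluor,M5,,0.85
L3,fluor,N,,0.15
L3,auger,M4,M5,0.5
L3,auger,M5,N,0.3
L3,auger,N,N,0.2
M1,fluor,N,,1
M1,auger,N,N,0.7
M1,auger,N,O,0.3
M2,fluor,N,,1
M2,auger,N,N,0.7
M2,auger,N,O,0.3
M3,fluor,N,,1
M3,auger,N,N,0.7
M3,auger,N,O,0.3
M4,fluor,N,,1
M4,auger,N,N,0.7
M4,auger,N,O,0.3
M5,fluor,N,,1
M5,auger,N,N,0.7
M5,auger,N,O,0.3
N,auger,O,O,1
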