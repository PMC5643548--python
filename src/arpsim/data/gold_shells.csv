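# Gold shell binding energies (keV) and fluorescence yields; N and O are effective merged shells, O is terminal
shell,binding_keV,fluorescence_yield
K,80.7,0.958
L1,14.35,0.1
L2,13.73,0.36
L3,11.92,0.32
M1,3.43,0.025
M2,3.15,0.025
M3,2.74,0.025
M4,2.29,0.025
M5,2.21,0.025
N,0.4,0
O,0.06,0
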