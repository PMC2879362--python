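element,radius,lj_epsilon,lj_sigma,default_charge
H,1.20,0.016,2.50,0.0
C,1.70,0.086,3.40,0.0
N,1.55,0.170,3.25,0.0
O,1.52,0.210,3.12,0.0
S,1.80,0.250,3.56,0.0
P,1.80,0.200,3.74,0.0
F,1.47,0.061,3.12,0.0
Cl,1.75,0.265,3.47,0.0
Br,1.85,0.320,3.66,0.0
I,1.98,0.400,3.88,0.0
Ca,1.71,0.460,3.05,2.0
Na,1.36,0.035,2.73,1.0
K,1.76,0.043,3.40,1.0
Mg,1.18,0.880,2.13,2.0
Zn,1.09,0.250,1.96,2.0
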