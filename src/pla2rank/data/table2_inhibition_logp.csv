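compound,log_p,ic50_hgiia_um,ic50_hgiia_sem,ic50_pgib_um
C1,3.81,5.0,0.7,>100
C2,5.59,10.0,1.5,>100
C3,2.88,5.0,1.2,>100
C4,4.57,6.5,1.8,>100
C5,3.91,2.5,0.5,>100
C6,5.59,3.0,0.2,>100
C7,3.64,35,1.8,>100
C8,7.13,0.62,0.15,>100
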