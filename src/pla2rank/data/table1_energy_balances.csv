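compound,e_int,d_e_prot,d_e_lig,d_e1,e_solv_complex,e_solv_lig,e_solv_prot,d_e_solv,d_e2
C1,-129.5,5.5,8.1,-115.9,-344.3,-22.5,-385.1,63.3,-52.6
C2,-131.8,7.8,10.6,-113.4,-343.6,-23.9,-385.1,65.4,-48.0
C3,-129.6,6.0,8.7,-114.9,-344.1,-22.7,-385.1,63.7,-51.2
C4,-130.1,5.6,8.0,-116.5,-343.7,-21.7,-385.1,63.1,-53.2
C5,-131.2,5.1,9.9,-116.2,-350.0,-21.8,-385.1,56.9,-59.3
C6,-130.8,10.0,9.5,-111.3,-350.1,-21.7,-385.1,56.7,-54.6
C7,-122.6,5.1,8.5,-109.0,-340.2,-21.8,-385.1,66.7,-42.3
C8,-135.1,7.1,9.8,-118.2,-349.7,-21.8,-385.1,57.2,-61.0
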