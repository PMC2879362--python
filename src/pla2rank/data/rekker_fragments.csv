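key,f,kind,notes
CH3,0.724,aliphatic,methyl
CH2,0.519,aliphatic,methylene
CH,0.113,aliphatic,methine
C6H5,1.902,aromatic,phenyl
C6H4,1.688,aromatic,phenylene (any substitution pattern)
C6H3,1.431,aromatic,trisubstituted benzene ring
H,0.204,aliphatic,hydrogen on heteroatom or fragment cap
O_al,-1.581,aliphatic,aliphatic ether oxygen
O_ar,-0.450,aromatic,ether oxygen attached to one aromatic ring
OH_al,-1.491,aliphatic,aliphatic hydroxyl
OH_ar,-0.343,aromatic,phenolic hydroxyl
OCH3_ar,0.274,aromatic,aryl methoxy
Cl_ar,0.922,aromatic,aromatic chlorine
Cl_al,0.057,aliphatic,aliphatic chlorine
NH_ar,-0.542,aromatic,aromatic secondary amine
oxadiazol-5-on-3-yl,-2.164,heteroaromatic,1.2.4-oxadiazol-5(4H)-one ring (neutral form); curated group value for this chemotype
indol-1-yl,1.622,heteroaromatic,N-linked indole; curated group value
5-chloroindol-1-yl,2.382,heteroaromatic,N-linked 5-chloroindole; curated group value
5-methoxyindol-1-yl,1.722,heteroaromatic,N-linked 5-methoxyindole; curated group value
"benzo-1,3-thiazol-2-yl",0.692,heteroaromatic,benzothiazole; curated group value
phenanthren-9-yl,5.392,aromatic,phenanthrene attached at C9; curated group value
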