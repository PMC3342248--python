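group,species_codes,class1,class2,class3,class4,class5
pine,PILA;PIPO,400,380,350,310,260
fir,ABCO;ABMA;ABPR;PSME,370,350,310,270,230
cedar,CADE,350,340,320,290,250
default,,360,340,300,260,220
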