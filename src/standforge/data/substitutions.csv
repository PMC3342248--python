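species,dbh_from_cm,proxy_species,components,cap_dbh_cm
ABCO,150,ABPR,bole,
ABCO,110,ABCO,branch;foliage,110
ABMA,110,ABMA,branch;foliage,110
PILA,0,PSME,branch;foliage,162
PILA,179.6,PSME,bole,
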