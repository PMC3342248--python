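species,component,form,c0,c1,dbh_min_cm,dbh_max_cm,rmse_log,source_id
ABCO,bole,log10_linear,-1.10,2.42,1,150,0.10,demo
ABCO,branch,log10_linear,-1.75,2.20,1,300,0.18,demo
ABCO,foliage,log10_linear,-1.60,1.90,1,300,0.20,demo
ABPR,bole,log10_linear,-1.05,2.42,10,300,0.12,demo
PILA,bole,log10_linear,-1.00,2.38,1,179.6,0.11,demo
PSME,bole,log10_linear,-1.08,2.40,10,300,0.10,demo
PSME,branch,log10_linear,-1.80,2.22,1,300,0.17,demo
PSME,foliage,log10_linear,-1.55,1.85,1,300,0.19,demo
CADE,bole,ln_linear,-2.30,2.35,1,300,0.22,demo
CADE,branch,ln_linear,-4.20,2.20,1,300,0.25,demo
CADE,foliage,ln_linear,-3.50,1.80,1,300,0.25,demo
ABMA,bole,log10_linear,-1.10,2.42,1,300,0.12,demo
ABMA,branch,log10_linear,-1.75,2.20,1,300,0.18,demo
ABMA,foliage,log10_linear,-1.60,1.90,1,300,0.20,demo
PIPO,bole,log10_linear,-1.05,2.40,1,300,0.10,demo
CONU,whole,log10_linear,-1.35,2.30,1,100,0.15,demo
QUKE,whole,log10_linear,-1.20,2.35,1,100,0.14,demo
PRSP,whole,log10_linear,-1.35,2.30,1,100,0.15,demo
SASC,whole,log10_linear,-1.40,2.25,1,100,0.20,demo
RHCA,whole,log10_linear,-1.40,2.25,1,100,0.20,demo
UNKN,whole,log10_linear,-1.20,2.40,1,300,0.15,demo
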