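phage_id,species,strong_pct,weak_pct,none_pct
241Ecol014PP,E. coli,33.3,22.2,44.4
303Ecol101PP,E. coli,27.8,22.2,50.0
308Ecol101PP,E. coli,44.4,5.6,50.0
310Ecol104PP,E. coli,44.4,11.1,44.4
348Ecol098PP,E. coli,50.0,5.6,44.4
351Saur083PP,S. aureus,40.0,20.0,40.0
355Saur083PP,S. aureus,86.7,6.7,6.7
357Saur119PP,S. aureus,26.7,13.3,60.0
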