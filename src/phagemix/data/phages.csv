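phage_id,short_name,host_species,family,genus,main_receptors,support_receptors
241Ecol014PP,241,E. coli,,Vequintavirus,LPS;unknown-porin,
303Ecol101PP,303,E. coli,Straboviridae,Tequatrovirus,LPS-core-A;OmpC,
308Ecol101PP,308,E. coli,Straboviridae,Mosigvirus,LPS-core-B;OmpC,
310Ecol104PP,310,E. coli,Straboviridae,Tequatrovirus,LPS-core-A;OmpA;PhoE,
348Ecol098PP,348,E. coli,Straboviridae,Mosigvirus,LPS-core-B;OmpC;OmpF;maltoporin,
351Saur083PP,351,S. aureus,Rountreeviridae,Rosenblumvirus,WTA-beta-GlcNAc,unknown-oligosaccharide
355Saur083PP,355,S. aureus,Herelleviridae,Kayvirus,WTA-beta-GlcNAc,unknown-oligosaccharide
357Saur119PP,357,S. aureus,Herelleviridae,Kayvirus,WTA-alpha-GlcNAc,unknown-oligosaccharide
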