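phage_id,predicted_receptors
303Ecol101PP,LPS-core;OmpC
310Ecol104PP,LPS-core;OmpA;PhoE
308Ecol101PP,LPS-core;OmpC
348Ecol098PP,LPS-core;OmpC;OmpF;maltoporin
241Ecol014PP,LPS;unknown-porin
351Saur083PP,WTA-beta-GlcNAc;other-polysaccharides
355Saur083PP,WTA-beta-GlcNAc;other-polysaccharides
357Saur119PP,WTA-alpha-GlcNAc;other-polysaccharides
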