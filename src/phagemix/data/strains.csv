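strain_id,species,uwm_id,year
090PP2016,E. coli,407,2016
091PP2016,E. coli,408,2016
092PP2016,E. coli,411,2016
093PP2016,E. coli,412,2016
094PP2016,E. coli,384,2016
095PP2016,E. coli,230,2016
096PP2016,E. coli,375,2016
097PP2016,E. coli,381,2016
098PP2016,E. coli,125,2016
099PP2016,E. coli,513,2016
100PP2016,E. coli,282,2016
101PP2016,E. coli,124,2016
103PP2016,E. coli,419,2016
104PP2016,E. coli,418,2016
117PP2016,E. coli,552,2016
118PP2016,E. coli,551,2016
132PP2017,E. coli,538,2017
133PP2017,E. coli,574,2017
058PP2016,S. aureus,377,2016
059PP2016,S. aureus,360,2016
060PP2016,S. aureus,342,2016
062PP2016,S. aureus,312,2016
063PP2016,S. aureus,322,2016
067PP2016,S. aureus,390,2016
069PP2016,S. aureus,522,2016
075PP2016,S. aureus,476,2016
076PP2016,S. aureus,227,2016
079PP2016,S. aureus,294,2016
080PP2016,S. aureus,165,2016
082PP2016,S. aureus,228,2016
083PP2016,S. aureus,536,2016
090PP2016,S. aureus,544,2016
091PP2016,S. aureus,556,2016
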