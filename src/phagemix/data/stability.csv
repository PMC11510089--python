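month,species,titer_pfu_ml
0,E. coli,2.16e8
0,S. aureus,1.28e8
3,E. coli,1.22e8
3,S. aureus,6.82e7
6,E. coli,1.25e8
6,S. aureus,7.31e7
9,E. coli,1.47e8
9,S. aureus,8.30e7
12,E. coli,9.16e7
12,S. aureus,4.42e7
15,E. coli,7.26e7
15,S. aureus,2.97e7
18,E. coli,1.12e8
18,S. aureus,3.43e7
21,E. coli,1.04e8
21,S. aureus,3.09e7
24,E. coli,1.04e8
24,S. aureus,3.42e7
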