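gene,receptor_class
ompC,OmpC
ompA,OmpA
wzzB,LPS-O-antigen
wbbD,LPS-O-antigen
tarS,WTA-beta-GlcNAc
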