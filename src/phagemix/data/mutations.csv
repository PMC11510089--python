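variant_id,gene,effect,product
119PP2018,tarS,stop_gained,Poly(ribitol-phosphate) beta-N-acetylglucosaminyltransferase TarS
119PP2018,5SrRNA,intergenic,5S ribosomal RNA (partial)
120PP2018,tarS,stop_gained,Poly(ribitol-phosphate) beta-N-acetylglucosaminyltransferase TarS
120PP2018,5SrRNA,intergenic,5S ribosomal RNA (partial)
121PP2018,tarS,missense,Poly(ribitol-phosphate) beta-N-acetylglucosaminyltransferase TarS
121PP2018,5SrRNA,intergenic,5S ribosomal RNA (partial)
235PP2017,ompC,frameshift,outer membrane porin C
1304PP2022,ompC,frameshift,outer membrane porin C
1304PP2022,wzzB,frameshift,regulator of length of O-antigen component of lipopolysaccharide chains
1306PP2022,ompC,stop_gained,outer membrane porin C
1306PP2022,wzzB,stop_gained,regulator of length of O-antigen component of lipopolysaccharide chains
265PP2018,ompA,frameshift,outer membrane protein 3a
265PP2018,wbbD,frameshift,"UDP-Gal:alpha-D-GlcNAc-diphosphoundecaprenol beta-1,3-galactosyltransferase"
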