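variant_id,species,parent_strain,inducing_phage,303Ecol101PP,308Ecol101PP,310Ecol104PP,348Ecol098PP,241Ecol014PP,351Saur083PP,355Saur083PP,357Saur119PP
227PP2017,E. coli,101PP2016,303Ecol101PP,-,+,+,+,-,x,x,x
228PP2017,E. coli,101PP2016,303Ecol101PP,-,+,+,+,-,x,x,x
229PP2017,E. coli,101PP2016,303Ecol101PP,-,+,+,+,-,x,x,x
230PP2017,E. coli,095PP2016,303Ecol101PP,-,-,+,+,+,x,x,x
1304PP2022,E. coli,095PP2016,303Ecol101PP,-,-,+,+,+,x,x,x
1306PP2022,E. coli,095PP2016,303Ecol101PP,-,-,+,+,+,x,x,x
235PP2017,E. coli,095PP2016,308Ecol101PP,+,-,+,+,+,x,x,x
236PP2017,E. coli,095PP2016,308Ecol101PP,+,-,+,+,+,x,x,x
237PP2017,E. coli,095PP2016,308Ecol101PP,+,-,+,+,+,x,x,x
241PP2017,E. coli,098PP2016,348Ecol098PP,-,+,+,-,+,x,x,x
242PP2017,E. coli,098PP2016,348Ecol098PP,-,-,-,-,+,x,x,x
243PP2017,E. coli,098PP2016,348Ecol098PP,-,-,-,-,+,x,x,x
244PP2017,E. coli,098PP2016,348Ecol098PP,-,-,-,-,+,x,x,x
261PP2018,E. coli,242PP2017,241Ecol014PP,-,+,-,+,-,x,x,x
262PP2018,E. coli,242PP2017,241Ecol014PP,-,+,-,-,-,x,x,x
263PP2018,E. coli,242PP2017,241Ecol014PP,-,+,-,-,-,x,x,x
264PP2018,E. coli,242PP2017,241Ecol014PP,-,-,-,-,-,x,x,x
265PP2018,E. coli,104PP2016,310Ecol104PP,-,+,-,-,+,x,x,x
266PP2018,E. coli,104PP2016,310Ecol104PP,-,+,-,-,+,x,x,x
300PP2018,E. coli,104PP2016,310Ecol104PP,-,+,-,-,+,x,x,x
119PP2018,S. aureus,083PP2016,351Saur083PP,x,x,x,x,x,-,-,+
120PP2018,S. aureus,083PP2016,351Saur083PP,x,x,x,x,x,-,-,+
121PP2018,S. aureus,083PP2016,351Saur083PP,x,x,x,x,x,-,-,+
122PP2018,S. aureus,083PP2016,351Saur083PP,x,x,x,x,x,-,-,+
123PP2018,S. aureus,083PP2016,355Saur083PP,x,x,x,x,x,-,-,+
124PP2018,S. aureus,083PP2016,355Saur083PP,x,x,x,x,x,-,-,+
125PP2018,S. aureus,083PP2016,355Saur083PP,x,x,x,x,x,-,-,+
126PP2018,S. aureus,083PP2016,355Saur083PP,x,x,x,x,x,-,-,+
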