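gene	role	protein_length	domains
APC	tsg
MLH1	tsg
MSH2	tsg
MSH6	tsg
PMS2	tsg
EPCAM	tsg
MUTYH	tsg
SMAD4	tsg
BMPR1A	tsg
STK11	tsg
PTEN	tsg
TP53	tsg
POLE	tsg
POLD1	tsg
CHEK2	tsg
ATM	tsg
GREM1	unknown
AXIN2	tsg
NTHL1	tsg
MSH3	tsg
KRAS	oncogene
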