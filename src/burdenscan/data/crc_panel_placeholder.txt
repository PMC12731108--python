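# Placeholder colorectal-cancer risk gene panel (21 genes).
#
# This is a generic, publicly known CRC/polyposis panel for demonstrating
# the gene-set burden test.  It is NOT the curated clinical panel a real
# analysis would use; supply your own list (one gene symbol per line) for
# production runs.
APC
MLH1
MSH2
MSH6
PMS2
EPCAM
MUTYH
SMAD4
BMPR1A
STK11
PTEN
TP53
POLE
POLD1
CHEK2
ATM
GREM1
AXIN2
NTHL1
MSH3
KRAS
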