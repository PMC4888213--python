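#oncointerp-kb v1
gene	cancer_type	role
APC	colorectal	tumor_suppressor
KRAS	colorectal	oncogene
NRAS	colorectal	oncogene
BRAF	colorectal	oncogene
PIK3CA	colorectal	oncogene
PTEN	colorectal	tumor_suppressor
EGFR	colorectal	oncogene
ALK	colorectal	oncogene
FLT3	colorectal	oncogene
AXIN1	colorectal	tumor_suppressor
DKK1	colorectal	tumor_suppressor
DKK2	colorectal	tumor_suppressor
CSNK1A1	colorectal	other
CTNNB1	colorectal	oncogene
PIK3CA	breast	oncogene
CCND1	breast	oncogene
MAP3K1	breast	tumor_suppressor
MAP2K4	breast	tumor_suppressor
PTEN	breast	tumor_suppressor
AKT1	breast	oncogene
AKT3	breast	oncogene
NF1	breast	tumor_suppressor
CDK1	breast	oncogene
RASA1	breast	tumor_suppressor
FGFR1	breast	oncogene
ERBB2	breast	oncogene
ESR1	breast	oncogene
NRAS	breast	oncogene
BRCA1	breast	tumor_suppressor
RET	MTC	oncogene
CDKN2A	MTC	tumor_suppressor
TP53	pan-cancer	tumor_suppressor
NF2	other-cancer	tumor_suppressor
TSC1	other-cancer	tumor_suppressor
PIK3R1	other-cancer	tumor_suppressor
INPP5D	other-cancer	tumor_suppressor
INPPL1	other-cancer	tumor_suppressor
RB1	other-cancer	tumor_suppressor
MTOR	other-cancer	oncogene
BRCA2	other-cancer	tumor_suppressor
ATM	other-cancer	tumor_suppressor
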