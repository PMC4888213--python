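#oncointerp-kb v1
pathway	genes
WNT	APC,DKK1,DKK2,CSNK1A1,AXIN1,CTNNB1
PI3K-AKT	PIK3CA,PIK3R1,PTEN,INPP5D,INPPL1,AKT1,AKT3,MTOR,TSC1,NF2
RTK-RAS-ERK	EGFR,ERBB2,KRAS,NRAS,BRAF,NF1,MAP2K1,MAP3K1,MAP2K4,RET,ALK,FLT3,FGFR1,RASA1,RASA3,EREG,AREG
cell-cycle	CCND1,CDK1,CDK4,CDK6,RB1,CDKN2A
DNA-repair	BRCA1,BRCA2,ERCC1,ERCC2,ERCC5,XRCC1,DCLRE1C,ATM,CHEK2,PALB2,TP53
angiogenesis	KDR,CXCR2
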