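#oncointerp-kb v1
name	mode	detects_germline	detects_expression	genes	hotspots
hotspot_cancer_panel	hotspot	false	false	KRAS,NRAS,BRAF,PIK3CA,EGFR,RET,TP53,APC,ALK	KRAS:5-70;NRAS:55-70;NRAS:110-120;BRAF:580-620;PIK3CA:530-560;PIK3CA:1040-1050;EGFR:700-900;RET:620-650;RET:900-930;TP53:120-290;APC:1250-1340;ALK:1170-1210
oncomine_like	full_gene	false	false	KRAS,NRAS,BRAF,PIK3CA,EGFR,RET,TP53,PTEN,ALK,FGFR1,CCND1,CDK4,CDK6,AKT1,ERBB2,FLT3,MTOR,MAP2K1,CDKN2A
foundation_like	full_gene_plus_cna	false	false	APC,KRAS,NRAS,BRAF,PIK3CA,PTEN,EGFR,TP53,RET,ALK,FLT3,FGFR1,CCND1,CDK4,CDK6,AKT1,AKT3,ERBB2,MTOR,NF1,NF2,TSC1,RB1,CDKN2A,BRCA1,BRCA2,MAP3K1,MAP2K4,RASA1,AXIN1,ATM,CHEK2,PALB2,KDR,PIK3R1,CTNNB1,ESR1,MAP2K1
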