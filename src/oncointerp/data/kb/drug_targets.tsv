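#oncointerp-kb v1
drug	gene	trigger	pathway	evidence	note
vandetanib	RET	activation	RTK-RAS-ERK	Strong	RET kinase inhibitor
cabozantinib	RET	activation	RTK-RAS-ERK	Strong	multi-kinase inhibitor
cabozantinib	FLT3	activation	RTK-RAS-ERK	Weak
crizotinib	ALK	activation	RTK-RAS-ERK	Moderate
ponatinib	FLT3	activation	RTK-RAS-ERK	Weak
quizartinib	FLT3	activation	RTK-RAS-ERK	Moderate
palbociclib	CCND1	activation	cell-cycle	Moderate	CDK4/6 inhibitor
palbociclib	CDK4	activation	cell-cycle	Moderate
ribociclib	CCND1	activation	cell-cycle	Moderate
dinaciclib	CDK1	activation	cell-cycle	Weak	investigational CDK inhibitor
trametinib	NF1	loss	RTK-RAS-ERK	Moderate	MEK inhibitor
trametinib	NRAS	activation	RTK-RAS-ERK	Moderate
trametinib	KRAS	activation	RTK-RAS-ERK	Moderate
trametinib	BRAF	activation	RTK-RAS-ERK	Moderate
vemurafenib	BRAF	activation	RTK-RAS-ERK	Strong
everolimus	PTEN	loss	PI3K-AKT	Moderate	mTOR inhibitor
everolimus	TSC1	loss	PI3K-AKT	Strong
everolimus	NF2	loss	PI3K-AKT	Moderate
everolimus	PIK3CA	activation	PI3K-AKT	Moderate
buparlisib	PIK3CA	activation	PI3K-AKT	Weak	pan-PI3K inhibitor
capivasertib	AKT1	activation	PI3K-AKT	Moderate
erlotinib	EGFR	activation	RTK-RAS-ERK	Strong
AZD4547	FGFR1	activation	RTK-RAS-ERK	Moderate
trastuzumab	ERBB2	activation	RTK-RAS-ERK	Strong
olaparib	BRCA1	germline	DNA-repair	Moderate	PARP inhibitor
olaparib	BRCA2	germline	DNA-repair	Moderate
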