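#oncointerp-kb v1
gene	protein_change
KRAS	p.G12V
KRAS	p.G12S
KRAS	p.G12D
KRAS	p.G12C
KRAS	p.G13D
KRAS	p.Q61H
NRAS	p.Q61R
NRAS	p.Q61P
NRAS	p.Q61K
NRAS	p.N116H
BRAF	p.V600E
PIK3CA	p.E542K
PIK3CA	p.E545K
PIK3CA	p.M1043I
PIK3CA	p.H1047R
EGFR	p.L858R
EGFR	p.G598V
EGFR	p.P596L
RET	p.C634R
RET	p.C634Y
RET	p.M918T
TP53	p.R273H
TP53	p.R273C
TP53	p.R248Q
TP53	p.G245S
TP53	p.Y220C
TP53	p.R282W
ALK	p.A1200V
ALK	p.F1174L
AKT1	p.E17K
ZZEF1	p.R500Q
TTN	p.A300V
MUC16	p.T100M
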