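#oncointerp-kb v1
gene	protein_change	effect
KRAS	p.G12V	activating
KRAS	p.G12S	activating
KRAS	p.G12D	activating
KRAS	p.G12C	activating
KRAS	p.G13D	activating
KRAS	p.Q61H	activating
KRAS	p.Q61L	activating
NRAS	p.Q61R	activating
NRAS	p.Q61P	activating
NRAS	p.Q61K	activating
NRAS	p.N116H	activating
BRAF	p.V600E	activating
PIK3CA	p.E542K	activating
PIK3CA	p.E545K	activating
PIK3CA	p.M1043I	activating
PIK3CA	p.H1047R	activating
RET	p.C634R	activating
RET	p.C634Y	activating
RET	p.M918T	activating
EGFR	p.L858R	activating
EGFR	p.D587H	activating
ALK	p.A1200V	activating
AKT1	p.E17K	activating
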