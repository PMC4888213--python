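#oncointerp-kb v1
marker_id	cancer_type	predicate	direction	note
PRG-CRC-01	colorectal	BRAF specific_protein_change p.V600E	unfavorable	BRAF p.V600E is associated with shorter survival in metastatic colorectal cancer
PRG-CRC-02	colorectal	NRAS somatic_activating	unfavorable	RAS-pathway activation predicts poorer outcome
PRG-MTC-01	MTC	RET specific_protein_change p.M918T	unfavorable	Somatic RET p.M918T marks aggressive medullary thyroid carcinoma
PRG-BRC-01	breast	ESR1 expression_high	favorable	ER-positive tumors respond to endocrine therapy
PRG-BRC-02	breast	CCND1 cna_gain	unfavorable	CCND1 amplification is linked to recurrence in ER-positive disease
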