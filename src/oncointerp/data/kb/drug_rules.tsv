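#oncointerp-kb v1
rule_id	drug	drug_tier	cancer_type	predicate	effect	evidence
CRC-CETX-01	cetuximab	1	colorectal	KRAS somatic_activating	lack_of_benefit	Definitive
CRC-CETX-02	cetuximab	1	colorectal	NRAS somatic_activating	lack_of_benefit	Strong
CRC-CETX-03	cetuximab	1	colorectal	BRAF specific_protein_change p.V600E	lack_of_benefit	Strong
CRC-CETX-04	cetuximab	1	colorectal	EREG expression_high AND AREG expression_high	benefit	Moderate
CRC-PANI-01	panitumumab	1	colorectal	KRAS somatic_activating	lack_of_benefit	Definitive
CRC-PANI-02	panitumumab	1	colorectal	NRAS somatic_activating	lack_of_benefit	Strong
CRC-PANI-03	panitumumab	1	colorectal	BRAF specific_protein_change p.V600E	lack_of_benefit	Strong
CRC-PANI-04	panitumumab	1	colorectal	EREG expression_high AND AREG expression_high	benefit	Moderate
CRC-BEV-01	bevacizumab	1	colorectal	KDR germline_variant	benefit	Moderate
CRC-BEV-02	bevacizumab	1	colorectal	CXCR2 germline_variant	benefit	Moderate
CRC-OXA-01	oxaliplatin	1	colorectal	ERCC1 germline_variant	lack_of_benefit	Moderate
CRC-OXA-02	oxaliplatin	1	colorectal	ERCC2 germline_variant	lack_of_benefit	Moderate
CRC-OXA-03	oxaliplatin	1	colorectal	ERCC5 germline_variant	lack_of_benefit	Moderate
CRC-OXA-04	oxaliplatin	1	colorectal	XRCC1 germline_variant	lack_of_benefit	Moderate
MTC-VAN-01	vandetanib	1	MTC	RET somatic_activating OR RET germline_variant	benefit	Definitive
MTC-CAB-01	cabozantinib	1	MTC	RET somatic_activating OR RET germline_variant	benefit	Definitive
BRC-CIS-01	cisplatin	1	breast	BRCA1 germline_variant	benefit	Strong
BRC-TRA-01	trastuzumab	1	breast	ERBB2 cna_gain OR ERBB2 expression_high	benefit	Definitive
BRC-TAM-01	tamoxifen	1	breast	ESR1 expression_high	benefit	Strong
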