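#oncointerp-kb v1
rule_id	drug	predicate	outcome
TOX-5FU-01	fluorouracil	DPYD germline_variant	Severe Toxicity
TOX-IRI-01	irinotecan	UGT1A1 germline_variant	Elevated Toxicity
TOX-OXA-01	oxaliplatin	ERCC1 germline_variant	Elevated Toxicity
TOX-OXA-02	oxaliplatin	GSTP1 germline_variant	Less Toxicity
TOX-CIS-01	cisplatin	ERCC2 germline_variant	Elevated Toxicity
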