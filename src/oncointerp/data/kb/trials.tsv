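#oncointerp-kb v1
trial_id	title	predicate	cancer_types	open	location
TRL-0001	CDK4/6 inhibitor in CCND1-amplified breast cancer	CCND1 cna_gain	breast	true	New York, NY
TRL-0002	AKT/mTOR inhibitor basket study	PIK3CA somatic_activating OR PTEN somatic_inactivating OR PTEN cna_loss	any	true	Boston, MA
TRL-0003	MEK inhibitor in RAS-altered solid tumors	KRAS somatic_activating OR NRAS somatic_activating	any	false	Houston, TX
TRL-0004	FGFR inhibitor in FGFR1-amplified tumors	FGFR1 cna_gain	any	true	New York, NY
TRL-0005	CDK1 inhibitor in CDK1-amplified tumors	CDK1 cna_gain	any	true	Chicago, IL
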