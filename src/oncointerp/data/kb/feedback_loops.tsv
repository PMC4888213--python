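#oncointerp-kb v1
gene_a	gene_b	combo	note
KRAS	PIK3CA	trametinib + buparlisib	MEK inhibition relieves feedback activation of PI3K
PTEN	KRAS	everolimus + trametinib	parallel-pathway lesions in ERK and PI3K axes
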