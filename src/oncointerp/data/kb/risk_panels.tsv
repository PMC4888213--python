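#oncointerp-kb v1
name	genes
breast-risk	BRCA1,BRCA2,TP53,PTEN,PALB2,CHEK2,ATM,DCLRE1C,NF1,STK11,CDH1,NBN,BARD1,BRIP1,RAD51C,RAD51D,MLH1,MSH2,MSH6,PMS2
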