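#oncointerp-kb v1
gene	chrom	start	aa_length
APC	chr5	112043201	2843
KRAS	chr12	25358180	189
NRAS	chr1	115251156	189
BRAF	chr7	140433812	766
PIK3CA	chr3	178866311	1068
PTEN	chr10	89623195	403
EGFR	chr7	55231251	1210
TP53	chr17	7572927	393
RET	chr10	43572517	1114
CDKN2A	chr9	21967751	156
RASA1	chr5	86563705	1047
RASA3	chr13	114747194	834
RB1	chr13	48877883	928
CCND1	chr11	69455873	295
MAP3K1	chr5	56111401	1512
MAP2K4	chr17	11924141	399
AKT1	chr14	105235686	480
AKT3	chr1	243651535	479
NF1	chr17	29421945	2818
NF2	chr22	29999545	595
CDK1	chr10	62538019	297
CDK4	chr12	58141510	303
CDK6	chr7	92234235	326
FGFR1	chr8	38268656	822
FLT3	chr13	28577411	993
ALK	chr2	29415640	1620
ERBB2	chr17	37844393	1255
BRCA1	chr17	41196312	1863
BRCA2	chr13	32889617	3418
DCLRE1C	chr10	14948870	692
KDR	chr4	55944644	1356
CXCR2	chr2	219027573	360
ERCC1	chr19	45910591	297
ERCC2	chr19	45854919	760
ERCC5	chr13	103697765	1186
XRCC1	chr19	44047464	633
DKK1	chr10	54074056	266
DKK2	chr4	107845817	259
CSNK1A1	chr5	148880763	337
AXIN1	chr16	337440	862
INPP5D	chr2	233925064	1189
INPPL1	chr11	71931721	1258
PIK3R1	chr5	67511584	724
TSC1	chr9	135766735	1164
EREG	chr4	75230859	169
AREG	chr4	75310852	252
ESR1	chr6	152011631	595
MTOR	chr1	11166588	2549
MAP2K1	chr15	66679211	393
PALB2	chr16	23614483	1186
CHEK2	chr22	29083731	543
ATM	chr11	108093559	3056
DPYD	chr1	97543300	1025
UGT1A1	chr2	234668879	533
GSTP1	chr11	67351066	210
CTNNB1	chr3	41240942	781
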