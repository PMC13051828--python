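gene_symbol	ensembl_id	upreg_p	os_p	pfs_p
CLMN	ENSG00000165959	0.0390
UBAP2L	ENSG00000143569	0.0305	<0.0001	0.0012
NEO1	ENSG00000067141	0.0280
PRKCA	ENSG00000154229	0.0199
ARHGEF9	ENSG00000131089	0.0166
DLG3	ENSG00000082458	0.0095	0.0032
UNC13B	ENSG00000198722	0.0031
MYLK	ENSG00000065534		0.029	0.016
OXCT1	ENSG00000083720		0.017	0.0009
IST1	ENSG00000182149		0.016
C1orf21	ENSG00000116667		0.014	0.0035
FTO	ENSG00000140718		0.013	0.023
SESTD1	ENSG00000187231		0.0057	0.03
NSD2	ENSG00000109685		0.00095	0.011
ATAD2	ENSG00000156802		<0.0001	<0.0001
CHEK1	ENSG00000149554		<0.0001	<0.0001
CIT	ENSG00000122966		<0.0001	<0.0001
HJURP	ENSG00000123485		<0.0001	<0.0001
KIF11	ENSG00000138160		<0.0001	<0.0001
TPX2	ENSG00000088325		<0.0001	<0.0001
APBB1IP	ENSG00000077420			0.011
ANKRD17	ENSG00000132466
CAMK1D	ENSG00000183049
CDYL2	ENSG00000166446
DENND5B	ENSG00000170456
EFR3B	ENSG00000084710
EIF2AK3	ENSG00000172071
ERC1	ENSG00000082805
ITPR1	ENSG00000150995
ITPR2	ENSG00000123104
KAT2B	ENSG00000114166
KIF13B	ENSG00000197892
MDGA2	ENSG00000139915
MYH10	ENSG00000133026
N4BP1	ENSG00000102921
NCKAP1L	ENSG00000123338
NEDD4L	ENSG00000049759
PDE4D	ENSG00000113448
SH3KBP1	ENSG00000147010
SMPD3	ENSG00000103056
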