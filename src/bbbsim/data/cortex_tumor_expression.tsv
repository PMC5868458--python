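Class	Protein	Endothelial cells	Glial cells	Neuronal cells	Neuropil	Not detected	Low	Medium	High
PI3K (Class 1a)	PIK3CB	Low	Medium	Medium	Medium	1/11	3/11	7/11	0
	PIK3R2	N/A	N/A	N/A	N/A	N/A	N/A	N/A	N/A
	PIK3CA	Low	Low	Medium	Low	0	0	10/11	1/11
	PIK3R1	Medium	Medium	High	Low	0	1/11	7/11	3/11
	PIK3CD	Not Detected	Not Detected	Not Detected	Not Detected	11/12	1/12	0	0
PI3K (Class 1b)	PIK3CG	N/A	N/A	N/A	N/A	N/A	N/A	N/A	N/A
PI3K (Class 2)	PIK3C2B	Not Detected	Not Detected	Not Detected	Not Detected	9/10	1/10	0	0
	PIK3C2A	Medium	Low	Medium	High	0	3/11	8/11	0
	PIK3C2G	N/A	N/A	N/A	N/A	N/A	N/A	N/A	N/A
TSC Complex	TSC1	Medium	Medium	Medium	Medium	0	1/12	6/12	5/12
	TSC2	Not Detected	Not Detected	Medium	Not Detected	4/10	5/10	1/10	0
BASC	MSH6	?	Low	Medium	Medium	5/12	4/12	1/12	2/12
BASC/BRCC	BRCA1	Medium	Low	Medium	Low	2/12	3/12	6/12	1/12
BRCC	BRCA2	N/A	N/A	N/A	N/A	2/12	2/12	7/12	1/12
CCNE-CDK2	CCNE1	High	Not Detected	Not Detected	Not Detected	0	9/12	2/12	1/12
	CDK2	Not Detected	Not Detected	Not Detected	Not Detected	5/11	5/11	1/11	0
CCND-CDK4	CDK4	N/A	N/A	N/A	N/A	N/A	N/A	N/A	N/A
CCND-CDK6	CDK6	Low	Not Detected	Not Detected	Not Detected	4/12	6/12	1/12	1/12
AKT	AKT1	Medium	Medium	High	Not Detected	0	4/11	3/11	4/11
	AKT2	High	Medium	High	Not Detected	0	1/12	6/12	5/12
	AKT3	Medium	Medium	High	Medium	0	4/11	5/11	2/11
FOXO	FOXO1	Low	Not Detected	Low	Medium	1/10	6/10	3/10	0
	FOXO3	Medium	Not Detected	Medium	?	2/12	6/12	4/12	0
	FOXO4	Not Detected	Not Detected	Not Detected	Not Detected	12/12	0	0	0
PDGFR	PDGFRA	High	Not Detected	Not Detected	Not Detected	8/12	2/12	2/12	0
	PDGFRB	Medium	Not Detected	Low	Not Detected	2/11	2/11	4/11	3/11
EGFR	ERBB3	Medium	Low	High	Medium	5/12	0	6/12	1/12
	EGFR	Not Detected	Not Detected	Not Detected	Not Detected	1/12	1/12	2/12	8/12
	ERBB2	Not Detected	Not Detected	Not Detected	Not Detected	10/12	1/12	0	1/12
FGFR	FGFR1	Low	Low	Low	Low	1/12	7/12	4/12	0
	FGFR2	Not Detected	Low	Medium	Not Detected	12/12	0	0	0
RTK	IGF1R	Not Detected	Not Detected	Not Detected	Not Detected	0	2/12	6/12	4/12
	MET	Not Detected	Not Detected	High	Low	0	5/12	7/12	0
RAS	NRAS	Medium	Low	Medium	Medium	0	2/12	10/12	0
	KRAS	Not Detected	Not Detected	Not Detected	Medium	12/12	0	0	0
	HRAS	Not Detected	High	High	High	0	2/12	4/12	6/12
RAF	ARAF	Low	Low	Low	Low	0	6/12	6/12	0
	BRAF	Low	Low	High	Medium	0	0	6/11	5/11
	RAF1	Not Detected	Low	Low	Not Detected	7/12	2/12	3/12	0
PKC	PRKCZ	Not Detected	Medium	High	Medium	0	6/11	5/11	0
	PRKCQ	N/A	N/A	N/A	N/A	N/A	N/A	N/A	N/A
	PRKCH	Medium	Medium	High	High	2/10	3/10	4/10	1/10
	PRKCG	Not Detected	Not Detected	Not Detected	Not Detected	10/12	2/12	0	0
	PRKCD	Low	Medium	Low	Low	1/12	3/12	6/12	2/12
	PRKCI	Not Detected	Not Detected	Medium	Not Detected	12/12	0	0	0
	PRKCB	Not Detected	Not Detected	Medium	Medium	5/12	6/12	0	1/12
	PRKCA	Not Detected	Low	Medium	Low	0	2/11	3/11	6/11
INK4	P16(CDKN2A)	Not Detected	Not Detected	Not Detected	Not Detected	2/12	3/12	5/12	2/12
	CDKN2B	Not Detected	Not Detected	Not Detected	Not Detected	1/12	1/12	8/12	2/12
	CDKN2C	Medium	Low	Medium	Medium	1/12	3/12	7/12	1/12
Protein	PDPK1	Not Detected	Not Detected	Low	Low	2/11	1/11	7/11	1/11
	PTEN	Low	Not Detected	Medium	High	4/9	4/9	1/9	0
	IRS1	Low	High	High	Not Detected	1/11	2/11	8/11	0
	SRC	Low	Not Detected	Not Detected	Low	4/12	4/12	3/12	1/12
	GAB1	N/A	N/A	N/A	N/A	N/A	N/A	N/A	N/A
	ERRFI1	Not Detected	Low	Medium	Low	7/10	3/10	0	0
	GRB2	Not Detected	Low	Medium	Low	1/11	2/11	4/11	4/11
	NF1	Low	Not Detected	High	Not Detected	0	1/10	6/10	3/10
	CBL	Low	Low	Low	Not Detected	0	0	9/9	0
	SPRY2	Not Detected	Low	Medium	Medium	9/12	0	3/12	0
	CDKN1A	Not Detected	Not Detected	Not Detected	Not Detected	7/11	1/11	3/11	0
	CDKN1B	Low	Medium	Medium	Low	2/12	2/12	2/12	6/12
	CCND1	Not Detected	Not Detected	Not Detected	Not Detected	10/12	0	2/12	0
	CCND2	Not Detected	Not Detected	Low	Low	8/12	4/12	0	0
	RB1	Low	Low	Medium	Not Detected	1/12	1/12	6/12	4/12
	E2F1	Medium	High	High	Not Detected	0	1/12	9/12	2/12
	ARF(CDKN2A)	Not Detected	Not Detected	Not Detected	Not Detected	2/12	3/12	5/12	2/12
	MDM2	High	High	High	Not Detected	0	0	0	12/12
	MDM4	Medium	Medium	High	Low	0	1/11	9/11	1/11
	TP53	Not Detected	Not Detected	Not Detected	Not Detected	1/11	4/11	3/11	3/11
	EP300	Low	Low	High	Not Detected	0	2/11	5/11	4/11
	ATM	Medium	Medium	Medium	Low	0	0	2/12	10/12
Small molecule	LPA	Not Detected	Not Detected	Not Detected	Not Detected	4/12	7/12	1/12	0
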