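# Synthetic stand-in KEGG pathway membership lists: real pathway ids and
# names, representative (not exhaustive, version-free) member gene symbols.
pathway_id	name	gene_symbol
hsa04520	Adherens junction	CDH1
hsa04520	Adherens junction	CTNNB1
hsa04520	Adherens junction	CTNNA1
hsa04520	Adherens junction	CTNND1
hsa04520	Adherens junction	WASF1
hsa04520	Adherens junction	EGFR
hsa04520	Adherens junction	MET
hsa04520	Adherens junction	SNAI1
hsa04520	Adherens junction	TCF7
hsa04520	Adherens junction	LEF1
hsa04520	Adherens junction	ACTN1
hsa04520	Adherens junction	VCL
hsa04210	Apoptosis	CASP3
hsa04210	Apoptosis	CASP8
hsa04210	Apoptosis	CASP9
hsa04210	Apoptosis	BAX
hsa04210	Apoptosis	BCL2
hsa04210	Apoptosis	BID
hsa04210	Apoptosis	APAF1
hsa04210	Apoptosis	TP53
hsa04210	Apoptosis	FAS
hsa04210	Apoptosis	TNF
hsa04210	Apoptosis	XIAP
hsa04210	Apoptosis	CYCS
hsa03410	Base excision repair	OGG1
hsa03410	Base excision repair	UNG
hsa03410	Base excision repair	APEX1
hsa03410	Base excision repair	POLB
hsa03410	Base excision repair	XRCC1
hsa03410	Base excision repair	LIG3
hsa03410	Base excision repair	MUTYH
hsa03410	Base excision repair	NEIL1
hsa03410	Base excision repair	PARP1
hsa03410	Base excision repair	FEN1
hsa04110	Cell cycle	CDK1
hsa04110	Cell cycle	CDK2
hsa04110	Cell cycle	CDK4
hsa04110	Cell cycle	CCNB1
hsa04110	Cell cycle	CCNE1
hsa04110	Cell cycle	CCND1
hsa04110	Cell cycle	CDC20
hsa04110	Cell cycle	PLK1
hsa04110	Cell cycle	BUB1
hsa04110	Cell cycle	MAD2L1
hsa04110	Cell cycle	E2F1
hsa04110	Cell cycle	RB1
hsa04110	Cell cycle	TP53
hsa04110	Cell cycle	WEE1
hsa04144	Endocytosis	EEA1
hsa04144	Endocytosis	RAB5A
hsa04144	Endocytosis	RAB7A
hsa04144	Endocytosis	CLTC
hsa04144	Endocytosis	AP2A1
hsa04144	Endocytosis	DNM1
hsa04144	Endocytosis	CAV1
hsa04144	Endocytosis	EPS15
hsa04144	Endocytosis	VPS4A
hsa04144	Endocytosis	CHMP2A
hsa04010	MAPK signaling pathway	MAPK1
hsa04010	MAPK signaling pathway	MAPK3
hsa04010	MAPK signaling pathway	MAP2K1
hsa04010	MAPK signaling pathway	RAF1
hsa04010	MAPK signaling pathway	KRAS
hsa04010	MAPK signaling pathway	HRAS
hsa04010	MAPK signaling pathway	JUN
hsa04010	MAPK signaling pathway	FOS
hsa04010	MAPK signaling pathway	DUSP1
hsa04010	MAPK signaling pathway	EGFR
hsa04010	MAPK signaling pathway	NRAS
hsa04010	MAPK signaling pathway	BRAF
hsa04010	MAPK signaling pathway	MAPK8
hsa04010	MAPK signaling pathway	MAPK14
hsa03420	Nucleotide excision repair	XPA
hsa03420	Nucleotide excision repair	XPC
hsa03420	Nucleotide excision repair	ERCC1
hsa03420	Nucleotide excision repair	ERCC2
hsa03420	Nucleotide excision repair	ERCC3
hsa03420	Nucleotide excision repair	DDB1
hsa03420	Nucleotide excision repair	DDB2
hsa03420	Nucleotide excision repair	RAD23B
hsa03420	Nucleotide excision repair	POLE
hsa03420	Nucleotide excision repair	LIG1
hsa04115	p53 signaling pathway	TP53
hsa04115	p53 signaling pathway	MDM2
hsa04115	p53 signaling pathway	CDKN1A
hsa04115	p53 signaling pathway	BAX
hsa04115	p53 signaling pathway	GADD45A
hsa04115	p53 signaling pathway	PUMA
hsa04115	p53 signaling pathway	SFN
hsa04115	p53 signaling pathway	SERPINB5
hsa04115	p53 signaling pathway	CCNG1
hsa04115	p53 signaling pathway	RRM2B
hsa04115	p53 signaling pathway	THBS1
hsa04310	Wnt signaling pathway	CTNNB1
hsa04310	Wnt signaling pathway	LEF1
hsa04310	Wnt signaling pathway	TCF7
hsa04310	Wnt signaling pathway	AXIN1
hsa04310	Wnt signaling pathway	AXIN2
hsa04310	Wnt signaling pathway	APC
hsa04310	Wnt signaling pathway	GSK3B
hsa04310	Wnt signaling pathway	WNT1
hsa04310	Wnt signaling pathway	WNT5A
hsa04310	Wnt signaling pathway	FZD7
hsa04310	Wnt signaling pathway	DKK1
hsa04310	Wnt signaling pathway	MYC
hsa04310	Wnt signaling pathway	CCND1
hsa04310	Wnt signaling pathway	NKD1
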