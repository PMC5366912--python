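# n_studies=7
# k=100
# min_studies=4
# direction=esc_high
Probesets	Gene ID	Overlapping number of probesets	Overlapping number of genes	Gene symbol	Gene names
243610_at	138255	7	7	C9orf135	chromosome 9 open reading frame 135
237911_at		6	6	BF057809	Transcribed locus
220184_at	79923	6	6	NANOG	Nanog homeobox
239975_at	3116	5	5	HLA-DPB2	major histocompatibility complex class II DP beta 2
216379_x_at	100133941	6	6	CD24	CD24 molecule
225846_at	54845	5	6	ESRP1	epithelial splicing regulatory protein 1
237192_at		5	5	AI435590	Transcribed locus
231381_at	790952	5	5	ESRG	embryonic stem cell related (non-protein coding)
230195_at	100131138	5	5	LINC01405	long intergenic non-protein coding RNA 1405
206286_s_at	6998	5	5	TDGF1	teratocarcinoma-derived growth factor 1
203453_at	6337	5	5	SCNN1A	sodium channel of non-voltage-gated 1 alpha subunit
1559280_a_at		5	5	AA483467	CDNA FLJ35259 fis clone PROST2004251
219955_at	54596	4	5	L1TD1	LINE-1 type transposase domain containing 1
1553874_a_at	84891	4	5	ZSCAN10	zinc finger and SCAN domain containing 10
231061_at		4	4	AI671581	Transcribed locus
230597_at	84889	4	4	SLC7A3	solute carrier family 7 member 3
214974_x_at	6374	4	4	CXCL5	chemokine (C-X-C motif) ligand 5
214240_at	51083	4	4	GAL	Galanin GMAP prepropeptide
210265_x_at	642559	4	4	POU5F1P3	POU class 5 homeobox 1 pseudogene 3
206424_at	1592	4	4	CYP26A1	cytochrome P450 family 26 subfamily A polypeptide 1
206309_at	11061	4	4	LECT1	leukocyte cell derived chemotaxin 1
206268_at	10637	4	4	LEFTY1	left-right determination factor 1
206002_at	10149	4	4	ADGRG2	adhesion G protein-coupled receptor G2
204891_s_at	3932	4	4	LCK	LCK proto-oncogene Src family tyrosine kinase
1554777_at	132625	3	5	ZFP42	ZFP42 zinc finger protein
242128_at	5015	3	4	OTX2	orthodenticle homeobox 2
235199_at	54941	3	4	RNF125	ring finger protein 125 E3 ubiquitin protein ligase
228038_at	6657	3	4	SOX2	Sex determining region Y box 2
206653_at	10622	3	4	POLR3G	polymerase RNA III polypeptide G
204286_s_at	5366	3	4	PMAIP1	phorbol-12-myristate-13-acetate-induced protein 1
201131_s_at	999	3	4	CDH1	cadherin 1 type 1 or epithelial E-cadherin
229724_at	2562	2	4	GABRB3	gamma-aminobutyric acid A receptor b3
202310_s_at	1277	2	4	COL1A1	collagen type I alpha 1
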