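variant_id	chrom	pos_hg38	end_hg38	rsid	ref	alt	gene	omim	hgvs_c	hgvs_p	phenotype	category
ABCC8:c.3989-9G>A	chr11	17397055		rs151344623	C	T	ABCC8	600509	NM_000352.6:c.3989-9G>A	splice acceptor	HYPERINSULINEMIC HYPOGLYCEMIA, FAMILIAL, 1
AGXT:c.731T>C	chr2	240875159		rs121908525	T	C	AGXT	604285	NM_000030.3:c.731T>C	NP_000021.1:p.Ile244Thr	PRIMARY HYPEROXALURIA TYPE 1	1
ARSA:c.449C>T	chr22	50627182		rs199476375	G	A	ARSA	607574	NM_000487.6:c.449C>T	NP_000478.3:p.Pro150Leu	METACHROMATIC LEUKODYSTROPHY	1
ARSA:c.854+3A>G	chr22	50626588		rs1057524566	T	C	ARSA	607574	NM_000487.6:c.854+3A>G	splice donor	METACHROMATIC LEUKODYSTROPHY	1
BLM:c.2208T>G	chr15	90766924		rs865899765	T	G	BLM	604610	NM_000057.4:c.2208T>G	NP_000048.1:p.Tyr736Ter	BLOOM SYNDROME
CFTR:c.3846G>A	chr7	117642566		rs77010898	G	A	CFTR	602421	NM_000492.4:c.3846G>A	NP_000483.3:p.Trp1282Ter	CYSTIC FIBROSIS
CFTR:c.254G>A	chr7	117509123		rs75961395	G	A	CFTR	602421	NM_000492.4:c.254G>A	NP_000483.3:p.Gly85Glu	CYSTIC FIBROSIS	1
CFTR:c.1624G>T	chr7	117587778		rs113993959	G	T	CFTR	602421	NM_000492.4:c.1624G>T	NP_000483.3:p.Gly542Ter	CYSTIC FIBROSIS
CFTR:c.1521_1523del	chr7	117559590		rs113993960	ATCT	A	CFTR	602421	NM_000492.4:c.1521_1523del	NP_000483.3:p.Phe508del	CYSTIC FIBROSIS	5
CFTR:c.2989-1G>A	chr7	117610518		rs397508470	G	A	CFTR	602421	NM_000492.4:c.2989-1G>A	splice acceptor	CYSTIC FIBROSIS
CNGB3:c.467C>T	chr8	86670970		rs139207764	G	A	CNGB3	605080	NM_019098.4:c.467C>T	NP_061971.3:p.Ser156Phe	ACHROMATOPSIA	1
COL6A2:c.1402C>T	chr21	46121067		rs374669775	C	T	COL6A2	120240	NM_001849.3:c.1402C>T	NP_001840.3:p.Arg468Ter	ULLRICH CONGENITAL MUSCULAR DYSTROPHY TYPE 1	1
CYP11B1:c.992C>T	chr8	142875841		rs1326688256	G	A	CYP11B1	610613	NM_000497.3:c.992C>T	NP_000488.3:p.Ala331Val	CONGENITAL ADRENAL HYPERPLASIA	1
DHCR7:c.964-1G>C	chr11	71435840		rs138659167	C	G	DHCR7	602858	NM_001360.3:c.964-1G>C	splice acceptor	SMITH-LEMLI-OPITZ SYNDROME
DSE:c.387delC	chr6	116399636		N/A	AC	A	DSE	605942	NM_013352.4:c.387delC	NP_037484.1:p.Tyr129Ter	EHLERS-DANLOS SYNDROME, MUSCULOCONTRACTURAL TYPE2	1
ESCO2:c.1674-2A>G	chr8	27803304		rs80359869	A	G	ESCO2	609353	NM_001017420.3:c.1674-2A>G	splice acceptor	ROBERTS SYNDROME	1
FAM161A:c.1567C>T	chr2	61839437		rs202193201	G	A	FAM161A	613596	NM_001201543.2:c.1567C>T	NP_001188472.1:p.Arg523Ter	RETINITIS PIGMENTOSA 28
FXN:GAA expansion	chr9	69037287		N/A	GAA	GAA>>	FXN	606829	NM_000144:GAA expansion	N/A	FRIEDREICH ATAXIA	1
G6PC:c.247C>T	chr17	42903947		rs1801175	C	T	G6PC1	613742	NM_000151.4:c.247C>T	NP_000142.2:p.Arg83Cys	GLYCOGEN STORAGE DISEASE TYPE 1A
GBA:c.1448T>C	chr1	155235252		rs421016	A	G	GBA	606463	NM_000157.4:c.1448T>C	NP_000148.2:p.Leu483Pro	GAUCHER DISEASE
GJB2:c.167del	chr13	20189414		rs80338942	CA	C	GJB2	121011	NM_004004.6:c.167del	NP_003995.2:p.Leu56fs	NONSYNDROMIC DEAFNESS	1
GJB2:c.269T>C	chr13	20189313		rs80338945	A	G	GJB2	121011	NM_004004.6:c.269T>C	NP_003995.2:p.Leu90Pro	NONSYNDROMIC DEAFNESS
GNE:c.2228T>C	chr9	36217399		rs28937594	A	G	GNE	603824	NM_001128227.3:c.2228T>C	NP_001121699.1:p.Met743Thr	INCLUSION BODY MYOPATHY (HIBM)	3
MLC1:c.176G>A	chr22	50084727		rs80358242	C	T	MLC1	605908	NM_015166.3:c.176G>A	NP_055981.1:p.Gly59Glu	MEGALENCEPHALIC LEUKOENCEPHALOPATHY WITH SUBCORTICAL CYSTS 1
MMACHC:c.271dup	chr1	45507544		rs398124292	T	TA	MMACHC	609831	NM_015506.3:c.271dup	NP_056321.2:p.Arg91fs	METHYLMALONIC ACIDURIA AND HOMOCYSTINURIA, cblC TYPE
NDUFS4:c.355G>C	chr5	53658555		rs747359752	G	C	NDUFS4	602694	NM_002495.4:c.355G>C	NP_002486.1:p.Asp119His	LEIGH SYNDROME TYPE 1	1
OTOF:c.5193-1G>A	chr2	26462182		rs111033373	C	T	OTOF	603681	NM_194248.3:c.5193-1G>A	splice acceptor	DEAFNESS, AUTOSOMAL RECESSIVE
OTOF:c.4227+1G>T	chr2	26467364		rs397515601	C	A	OTOF	603681	NM_194248.3:c.4227+1G>T	splice donor	DEAFNESS, AUTOSOMAL RECESSIVE
PEX2:c.355C>T	chr8	76983824		rs61752123	G	A	PEX2	170993	NM_000318.3:c.355C>T	NP_000309.2:p.Arg119Ter	PEROXISOME BIOGENESIS DISORDER 5A (ZELLWEGER)
SMPD1:c.1829G>A	chr11	6394540		rs140269316	G	A	SMPD1	607608	NM_000543.5:c.1829G>A	NP_000534.3:p.Arg610His	NIEMANN-PICK DISEASE
SMPD1:c.1826_1828GCC	chr11	6394536		rs120074118	TGCC	T	SMPD1	607608	NM_000543.5:c.1826_1828GCC	NP_000534.3:p.Arg610del	NIEMANN-PICK DISEASE
TRPM1:36.8KB DEL	chr15	31062999	31099445	N/A	N/A	N/A	TRPM1	603576	36.8KB DEL, EX2-7	N/A	CONGENITAL STATIONARY NIGHT BLINDNESS
VAC14:c.2005G>T	chr16	70695574		rs1363536856	C	A	VAC14	604632	NM_018052.5:c.2005G>T	NP_060522.3:p.Val669Leu	STRIATONIGRAL DEGENERATION	1
AIRE:c.254A>G	chr21	44286678		rs179363882	A	G	AIRE	607358	NM_000383.4:c.254A>G	NP_000374.1:p.Tyr85Cys	AUTOIMMUNE POLYENDOCRINOPATHY	2
BLM:c.98+1G>T	chr15	90747491		rs750293380	G	T	BLM	604610	NM_001287246.2:c.98+1G>T	splice donor	BLOOM SYNDROME	1
CNGA3:c.1585G>A	chr2	98396755		rs104893619	G	A	CNGA3	600053	NM_001298.3:c.1585G>A	NP_001289.1:p.Val529Met	ACHROMATOPSIA	4
GPT2:c.159C>G	chr16	46906858		rs786203999	C	G	GPT2	138210	NM_133443.4:c.459C>G	NP_597700.1:p.Ser153Arg	DEVELOPMENTAL ENCEPHALOPATHY	1
LIPA:c.260G>T	chr10	89228368		rs587778878	C	A	LIPA	613497	NM_000235.4:c.260G>T	NP_000226.2:p.Gly87Val	WOLMAN'S DISEASE	2
TYMP:c.433G>A	chr22	50528595		rs121913037	C	T	TYMP	131222	NM_001953.5:c.433G>A	NP_001944.1:p.Gly145Arg	MNGIE-MITOCHONDRIAL NEUROGASTROINTESTINAL ENCEPHALOMYOPATHY	4
USH2A:c.236_239dup	chr1	216422097		rs1553258097	G	GGTAC	USH2A	608400	NM_007123.5:c.236_239dup	NP_009054.5:p.Gln81fs	USHER SYNDROME TYPE 2A	4
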