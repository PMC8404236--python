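variant_id	category	syrian_mixed	syrian_mixed_pct	iranian_mixed	iranian_mixed_pct	ashkenazi	ashkenazi_pct
COL6A2:c.1402C>T	1	56/3401	1.65	ND	ND	29/10125	0.29
GJB2:c.167del	1	41/3401	1.21	3/1112	0.27	1078/41414	2.60
FXN:GAA expansion	1	19/3401	0.56	ND	ND	26/9208	0.28
CYP11B1:c.992C>T	1	9/3401	0.26	2/3010	0.07	6/60345	0.01
NDUFS4:c.355G>C	1	6/3401	0.18	2/3132	0.06	16/67454	0.02
VAC14:c.2005G>T	1	5/3401	0.15	0/1087	0.00	0/39212	0.00
ESCO2:c.1674-2A>G	1	4/3401	0.12	0/3010	0.00	7/61630	0.01
CNGB3:c.467C>T	1	4/3401	0.12	3/2904	0.10	37/59336	0.06
BLM:c.98+1G>T	1	1/3401	0.03	0/1088	0.00	1/39219	0.00
ARSA:c.854+3A>G	1	1/3401	0.03	0/3010	0.00	1/61747	0.00
ARSA:c.449C>T	1	1/3401	0.03	0/3236	0.00	8/67953	0.01
AGXT:c.731T>C	1	1/3401	0.03	0/347	0.00	2/27885	0.01
CFTR:c.254G>A	1	0/3401	0.00	1/3576	0.03	4/117781	0.00
GPT2:c.159C>G	1	0/3401	0.00	0/3007	0.00	1/61586	0.00
DSE:c.387delC	1	0/3401	0.00	0/342	0.00	0/27799	0.00
AIRE:c.254A>G	2	9/3401	0.26	55/3761	1.46	18/73327	0.02
LIPA:c.260G>T	2	1/3401	0.03	15/1435	1.05	8/40987	0.02
GNE:c.2228T>C	3	24/3401	0.71	120/3147	3.81	61/67615	0.09
TYMP:c.433G>A	4	4/3401	0.12	34/3747	0.91	10/73272	0.01
USH2A:c.236_239dup	4	2/3401	0.06	18/3588	0.50	10/65282	0.02
CNGA3:c.1585G>A	4	1/3401	0.03	11/3761	0.29	9/73408	0.01
CFTR:c.1521_1523del	5	19/3401	0.56	25/5279	0.47	4303/370954	1.16
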