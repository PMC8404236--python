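variant_id	syrian_full	syrian_full_pct	ashkenazi	ashkenazi_pct
ABCC8:c.3989-9G>A	1/339	0.29	3969/235602	1.68
AGXT:c.731T>C	4/369	1.08	0/21050	0.00
ARSA:c.449C>T	5/376	1.33	1/51587	0.00
ARSA:c.854+3A>G	5/376	1.33	0/46388	0.00
BLM:c.2208T>G	1/404	0.25	3265/335777	0.97
CFTR:c.3846G>A	3/435	0.69	6721/335635	2.00
CFTR:c.254G>A	2/381	0.52	0/97562	0.00
CFTR:c.1624G>T	2/435	0.46	737/335635	0.22
CFTR:c.1521_1523del	2/438	0.46	3965/335635	1.18
CFTR:c.2989-1G>A	1/329	0.30	0/223335	0.00
CNGB3:c.467C>T	7/376	1.86	26/44392	0.06
COL6A2:c.1402C>T	13/331	3.93	0/5922	0.00
CYP11B1:c.992C>T	10/376	2.66	0/44988	0.00
DHCR7:c.964-1G>C	2/227	0.88	2016/88773	2.27
DSE:c.387delC	1/369	0.27	0/21009	0.00
ESCO2:c.1674-2A>G	2/376	0.53	0/51519	0.00
FAM161A:c.1567C>T	3/154	1.95	1/49492	0.00
FXN:GAA expansion	3/331	0.91	14/5109	0.27
G6PC:c.247C>T	2/397	0.50	4816/335799	1.43
GBA:c.1448T>C	1/101	0.99	88/72333	0.12
GJB2:c.167del	8/368	2.17	929/32870	2.83
GJB2:c.269T>C	1/104	0.96	7/32171	0.02
GNE:c.2228T>C	8/376	2.13	1/51647	0.00
MLC1:c.176G>A	1/273	0.37	0/53648	0.00
MMACHC:c.271dup	1/154	0.65	372/49724	0.75
NDUFS4:c.355G>C	2/376	0.53	0/46275	0.00
OTOF:c.5193-1G>A	4/101	3.96	0/30796	0.00
OTOF:c.4227+1G>T	1/102	0.98	0/30826	0.00
PEX2:c.355C>T	1/154	0.65	379/49883	0.76
SMPD1:c.1829G>A	1/93	1.08	0/25901	0.00
SMPD1:c.1826_1828GCC	2/380	0.53	66/304382	0.02
TRPM1:36.8KB DEL	2/133	1.50	946/37796	2.50
VAC14:c.2005G>T	1/367	0.27	0/30779	0.00
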