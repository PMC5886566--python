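pair	kit	n_ff	n_ffpe	n_pos	n_co	n_di
1	QIAamp	41008	40165	39778	39772	6
2	QIAamp	40902	40157	39691	39685	6
3	QIAamp	40950	40361	39913	39906	7
4	QIAamp	41078	40011	39643	39639	4
5	QIAamp	40705	40295	39355	39351	4
6	QIAamp	40999	40134	39570	39567	3
7	QIAamp	40571	40481	39634	39629	5
8	QIAamp	40568	40623	39568	39564	4
9	GeneRead	41008	40716	40075	40068	7
10	GeneRead	40902	40764	40048	40044	4
11	GeneRead	40902	40712	40004	40001	3
12	GeneRead	40950	40712	40094	40089	5
13	GeneRead	41078	40788	40102	40098	4
14	GeneRead	41078	40779	40116	40110	6
15	GeneRead	40705	40794	39631	39626	5
16	GeneRead	40999	40852	40046	40042	4
17	GeneRead	40571	40586	39473	39468	5
18	GeneRead	40568	41009	39848	39844	4
19	Maxwell	41239	37396	36851	36846	5
20	Maxwell	41201	37834	37239	37236	3
21	Maxwell	41115	37721	37185	37179	6
22	Maxwell	41189	36215	35751	35745	6
23	Maxwell	40963	38097	37588	37582	6
24	Maxwell	41074	38132	37577	37572	5
25	Maxwell	41133	38369	37860	37858	2
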