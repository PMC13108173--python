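rank	mirna	expr_pct_per_year	expr_direction	meth_pct_per_year	meth_status	conc_score	covariate_robust
1	miR-519a-1	0.174	Up	-0.122	Hypo	2.489	False
2	miR-129-2	-2.612	Down	0.268	Hyper	2.102	True
3	miR-6720	-1.525	Down	0.281	Hyper	1.763	False
4	miR-767	4.36	Up	-0.32	Hypo	0.687	True
5	miR-378a	-1.134	Down	0.11	Hyper	0.635	False
6	miR-499a	-3.059	Down	0.062	Hyper	0.545	True
7	miR-328	-1.187	Down	0.012	Hyper	0.082	False
8	miR-483	18.35	Up	-0.006	Hypo	0.079	True
9	miR-4677	1.189	Up	-0.025	Hypo	0.054	False
10	miR-153-2	1.387	Up	-0.022	Hypo	0.042	True
11	miR-486-2	1.652	Up	-0.022	Hypo	0.034	False
12	miR-486-1	1.741	Up	-0.022	Hypo	0.031	False
13	miR-339	1.098	Up	-0.014	Hypo	0.029	True
14	miR-577	3.017	Up	-0.105	Hypo	0.025	False
15	miR-5683	2.595	Up	-0.069	Hypo	0.024	False
16	miR-592	3.566	Up	-0.02	Hypo	0.018	False
17	miR-425	1.967	Up	-0.014	Hypo	0.015	True
18	miR-7-2	4.383	Up	-0.006	Hypo	0.008	True
19	miR-3651	2.312	Up	-0.008	Hypo	0.004	True
20	miR-96	1.426	Up	-0.004	Hypo	0.004	True
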