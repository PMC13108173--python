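rank	mirna	expr_direction	expr_concordance	meth_status	meth_concordance
1	miR-519a-1	NA	No	Hypo	Yes
2	miR-129-2	Down	Yes	Hyper	Yes
3	miR-6720	Down	Yes	NA	No
4	miR-767	Up	Yes	NA	No
5	miR-378a	NA	No	NA	No
6	miR-499a	Up	No	NA	No
7	miR-328	Up	No	Hypo	No
8	miR-483	Up	Yes	Hyper	No
9	miR-4677	NA	No	NA	No
10	miR-153-2	Up	Yes	Hypo	Yes
11	miR-486-2	Down	No	Hypo	Yes
12	miR-486-1	Down	No	Hypo	Yes
13	miR-339	Up	Yes	Hypo	Yes
14	miR-577	Up	Yes	Hyper	No
15	miR-5683	NA	No	NA	No
16	miR-592	Up	Yes	Hypo	Yes
17	miR-425	Down	No	Hypo	Yes
18	miR-7-2	Down	No	Hypo	Yes
19	miR-3651	NA	No	NA	No
20	miR-96	Down	No	Hyper	Yes
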