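chromosome	chromosome_bp	n_contigs	n_contigs_es_only	largest_contig_bp	pct_covered	n_tiling_clones	n_consistent	n_consistent_es_only	n_one_end	n_inconsistent	n_rearrangements	n_confirmed	n_genes	pct_genes_covered
I	28185914	34	58	6029661	84.8	271	1465	802	1759	98	12	9	1253	80.5
II	23295652	28	44	4235816	90.0	227	1254	772	1399	77	8	5	853	85.2
III	16798506	24	29	3575021	85.5	161	874	510	1199	93	17	17	923	86.5
IV	32632948	42	62	7720774	86.6	313	1593	883	2012	111	10	8	1317	88.3
V	12251397	16	28	1931357	88.5	121	731	418	784	57	6	2	733	88.4
VI	17083675	24	36	8860934	85.3	162	993	678	1052	64	9	1	749	78.2
VII	27937443	43	65	4327197	89.3	281	1486	849	1855	97	14	10	1311	86.7
VIII	19368704	30	44	4711769	85.8	188	869	517	1002	110	10	5	876	83.4
IX	20249479	37	45	3058355	82.9	195	855	448	1190	84	12	9	1009	80.0
X	15657440	31	37	1368409	84.2	152	712	410	897	90	16	13	802	81.2
XI	16706052	30	27	4014839	83.3	155	816	494	1101	81	13	7	1050	83.5
XII	18401067	27	35	4710925	88.5	177	902	559	1211	58	12	9	1000	86.8
XIII	20083130	26	38	3478171	90.6	194	1121	678	1194	42	9	3	970	89.6
XIV	15246461	18	33	3545956	88.0	150	792	414	931	59	6	2	738	85.2
XV	16198764	20	29	3426120	89.3	156	969	619	1017	73	10	9	779	87.9
XVI	18115788	24	38	6616511	88.4	182	916	533	1163	47	8	4	799	88.5
XVII	14603141	30	30	3516936	88.5	163	784	459	1110	37	6	4	698	85.5
XVIII	16282716	35	43	1934982	83.6	170	783	373	989	68	12	6	761	82.7
XIX	20240660	38	43	2450075	86.6	206	1004	628	1204	104	14	8	1037	82.5
XX	19732071	22	35	7220725	90.3	194	1077	639	1178	30	8	6	927	89.5
XXI	11717487	9	17	4139228	87.4	111	639	393	693	7	2	2	460	93.9
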