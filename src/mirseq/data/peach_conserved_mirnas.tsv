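#family	sequence	length	LC	LS	RC	RS	printed_log2fc_leaf	printed_log2fc_root
miR156	UGACAGAAGAGAGUGAGCAC	20	934112	1346985	68360	81033	0.84	0.18
miR159	UUUGGAUUGAAGGGAGCUCUA	21	3033	1889	2176	489	-0.36	NA
miR160	GCGUACGAGGAGCCAAGCAUA	21	2969	2235	2118	13332	-0.09	NA
miR162	UCGAUAAACCUCUGCAUCCAG	21	321	310	261	92	0.26	NA
miR164	UGGAGAAGCAGGGCACGUGCA	21	13187	13085	9571	3088	0.304	NA
miR166	UCGGACCAGGCUUCAUUCCCC	21	144793	176391	158327	109345	0.60	-0.59
miR167	UGAAGCUGCCAGCAUGAUCUG	21	92812	71576	83715	5571	0.058	NA
miR168	UCGCUUGGUGCAGGUCGGGAA	21	20085	21168	14751	16549	0.391	0.109
miR169	UGAGCCAAGAAUGACUUGCUG	21	907	804	1420	94	0.141	NA
miR171	UUGAGCCGCGUCAAUAUCUCC	21	262	128	90	393	-0.707	NA
miR172	AGAAUCUUGAUGAUGCUGCAU	21	2874	1891	1719	1212	-0.288	-0.560
miR319	UUGGACUGAAGGGAGCUCCC	20	106	124	83	9	0.542	NA
miR390	AAGCUCAGGAGGGAUAGCGCC	21	4098	5471	1862	2659	0.732	0.457
miR396	GCUCAAGAAAGCUGUGGGAGA	21	2993	3033	3388	539	0.355	NA
miR397	UCAUUGAGUGCAGCGUUGAUG	21	10464	11428	36291	4151	0.443	NA
miR398	UGUGUUCUCAGGUCGCCCCUG	21	1741	1569	10259	586	0.165	NA
miR399	UGCCAAAGAAGAGUUGCCCUA	21	103	91	36	27	0.137	-0.471
miR403	UUAGAUUCACGCACAAACUCG	21	140	144	109	54	0.356	NA
miR408	ACAGGGAACAGGUAGAGCAUG	21	77621	55268	71947	34715	-0.174	NA
miR415	AAAGAUCCAGAAACAGAGCAG	21	806	516	2	24	-0.327	NA
miR419	UGAUGAUGCUGACGAUGACGA	21	52	15	54	66	NA	0.233
miR472	UCUUUCCCAAUCCACCCAUGCC	22	837	676	1408	99	0.007	NA
miR479	UGUGAUAUUGGUUCGGUUCAU	21	43	21	12	428	-0.718	NA
miR535	UGACGACGAGAGAGAGCACGC	21	989554	1438413	604358	277182	0.855	NA
miR2118	CUACCGAUUCCACCCAUUCCGA	22	1358	1345	4343	1897	0.301	NA
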