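region_no	chrom	start_mb	end_mb	n_total_snps	n_basn_snps
1	13	53.25	53.3	280	42
2	4	151.55	151.6	189	28
3	1	86.2	86.25	254	34
4	15	37.05	37.1	347	40
5	1	180.4	180.45	302	34
6	13	53.2	53.25	267	29
7	4	142.95	143	329	30
8	1	61.6	61.65	253	23
9	15	57.95	58	332	29
10	2	109.15	109.2	305	25
11	10	105.6	105.65	313	25
12	1	180.35	180.4	327	26
13	1	180.45	180.5	306	24
14	11	61.1	61.15	217	16
15	17	72.85	72.9	383	28
16	14	79.55	79.6	290	21
17	7	158.15	158.2	444	32
18	11	61.05	61.1	222	16
19	12	71.95	72	352	25
20	6	168.9	168.95	493	34
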