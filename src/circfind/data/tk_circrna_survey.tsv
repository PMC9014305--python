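locus_name	circ_start	circ_end	predicted_length	wt_aligned	wt_circ	ko_aligned	ko_circ	wt_circ_total	ko_circ_total	reported_depleted
sR01	47786	47847	62	2167	395	1776	7	18	0	True
sR05	116401	116466	66	445142	354	333035	0	54	0	True
sR13	279797	279863	67	59144	47	58048	0	2	0	True
sR15	316130	316191	62	1629229	698	1523609	8	113	0	True
sR20	558818	558879	62	1622	21	1400	0	46	0	True
sR28	832364	832425	62	65322	72	54801	1	123	0	True
sR29	940146	940209	64	475600	36	283215	0	11	0	True
sR31	963853	963919	67	562648	4655	721884	34	343	1	True
sR34	1103565	1103626	62	20161	119	19347	0	14	0	True
sR37	1159583	1159644	62	356961	44	195173	1	21	0	True
sR38	1167276	1167338	63	11287	106	4940	0	3	0	True
sR41	1226838	1226899	62	1967	31	610	0	202	0	True
sR42	1226948	1227017	70	12085	7194	17658	10	145	0	True
sR46	1371729	1371790	62	176232	188	79569	3	258	3	True
sR49	1446209	1446268	60	62328	358	36039	1	376	0	True
sR52	1476851	1476917	67	28701	467	42613	6	4	0	True
sR58	1947796	1947856	61	926	95	845	0	5	0	True
sR61	2070055	2070116	62	100212	92	31284	0	22	0	True
ncRNA01	1053772	1053834	63	1267983	68	587087	3	48	0	True
ncRNA02	1257020	1257081	62	8320	139	6342	0	135	0	True
ncRNA03	1593064	1593134	71	7565	403	9633	1	4	0	True
TK0058	51411	51477	67	1816	589	780	1	493	1	True
TK2034	1826865	1826930	66	771	66	477	2	22	0	True
TK2109	1894519	1894579	61	14240	28	11134	0	857	4	True
tRNA-Trp	1945728	1945789	62	28907	2023	23156	1292	1415	987	False
TK0135	108461	116468	8008	457060	90	576950	110	0	0	False
TK0894	779653	779796	144	317	28	215	28	0	0	False
TK1980	1784662	1785579	918	1322	42	739	53	0	0	False
16S RNA-c1	2022801	2024382	1582	404505	96319	268720	53186	6836	4733	False
23S RNA-c1	2024584	2027631	3048	867077	27733	610944	11628	282955	205719	False
23S RNA-c2	2024595	2027605	3011	867051	83	610939	35	42016	23246	False
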