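amplicon	start	end	size	genes
1	85669352	85675348	5996	--
2	90176250	90233199	56949	PFTK1
3	92170683	92181579	10896	--
4	92402830	92489679	86849	CDK6
5	92525776	92559603	33827	--
6	92621928	92628443	6515	--
7	94153659	94160414	6755	CASD1
8	94187248	94227832	40584	SGCE
9	95575453	95593279	17826	DYNC1I1
10	95625240	95626171	931	DYNC1I1
11	95626365	95634906	8541	DYNC1I1
12	95857177	95888724	31547	SLC25A13
13	95984342	95992052	7710	--
14	96016428	96091391	74963	--
15	96091675	96098719	7044	--
16	96223512	96436326	212814	SHFM1
17	96566511	96585224	18713	--
18	100008093	100031196	23103	ZCWPW1,MEPCE
19	100188936	100202216	13280	FBXO24,PCOLCE
20	100212010	100322730	110720	MOSPD3,TFR2,ACTL6B,GNB2,GIGYF1,POP7,EPO
21	100514082	100516140	2058	--
22	100594842	100615369	20527	MUC12
23	100619990	100633128	13138	MUC12
24	100899076	100900255	1179	--
25	100920401	100933959	13558	--
26	101043124	101046675	3551	EMID2
27	101047291	101056595	9304	EMID2
28	101542859	101587823	44964	CUX1
29	101708443	101725375	16932	CUX1
30	116320004	116359562	39558	MET
31	116359697	116359984	287	MET
32	116516633	116651559	134926	CAPZA2,ST7,ST7OT1,ST7OT4
33	116832388	116859422	27034	ST7,ST7OT3
34	116986284	117113342	127058	ASZ1
35	117258567	117275904	17337	CFTR
36	117301541	117312368	10827	CFTR
37	117348151	117357569	9418	CTTNBP2
38	117371511	117376667	5156	CTTNBP2
39	117487299	117511084	23785	CTTNBP2
40	117575700	117576160	460	--
41	117604668	117718500	113832	--
42	117727390	117773948	46558	--
43	117862904	117882935	20031	ANKRD7
44	117888893	117908976	20083	--
45	118228295	118274830	46535	--
46	118275399	118309895	34496	--
47	118442613	118473838	31225	--
48	118574464	118640670	66206	--
49	149702946	149746115	43169	--
50	153635222	153636533	1311	DPP6
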