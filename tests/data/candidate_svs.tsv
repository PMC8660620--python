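id	chrom	start	end	length	svtype	location	gene
sv_20920	12	53161161	53161400	239	DEL	EXON=37/37,STRAND=1	CHD3
sv_12600	7	24102759	24102912	153	DUP	EXON=26/44,INTRON=26/43,STRAND=-1	TNXB
sv_10846	6	57942591	57942680	89	DEL	EXON=7/16,INTRON=6/15,STRAND=-1	PPP2R1A
sv_03787	2	48671743	48672091	348	DEL	EXON=7/22,INTRON=7/21,STRAND=1	EIF4G2
sv_03788	2	48672667	48672980	313	DEL	EXON=10/22,INTRON=10/21,STRAND=1	EIF4G2
sv_03789	2	48673120	48673212	92	DEL	EXON=11/22,INTRON=11/21,STRAND=1	EIF4G2
sv_03790	2	48675413	48675496	83	DEL	EXON=16/22,INTRON=16/21,STRAND=1	EIF4G2
sv_07880	4	93902799	93902892	93	DEL	EXON=11/15,INTRON=10/14,STRAND=-1	LMNA
sv_06002	3	76867706	76867956	250	DEL	EXON=6/7,INTRON=6/6,STRAND=1	RAB1A
sv_14248	8	20162216	20162373	157	DEL	EXON=11/11,INTRON=10/10,STRAND=1	RBPJ
sv_24885	14	113163523	113163523	63	INS	EXON=10/14,STRAND=1	NOLC1
sv_07254	4	36223670	36223968	298	DEL	EXON=11/18,INTRON=11/17,STRAND=1	PABPC1
sv_07255	4	36224682	36224763	81	DEL	EXON=13/18,INTRON=13/17,STRAND=1	PABPC1
sv_08996	5	33175088	33175088	88	INS	EXON=19/19,STRAND=1	MDM2
sv_20346	12	17659189	17659247	58	DEL	INTRON=1/4,STRAND=-1	WNT3
sv_01051	1	74645288	74645365	77	DEL	INTRON=2/3,STRAND=1	FOXO3
sv_07988	4	103498496	103498560	64	DEL	INTRON=3/7,STRAND=1	VTCN1
sv_05472	3	27283820	27284082	262	DEL	INTRON=3/11,STRAND=-1	XYLT1
sv_13380	7	89601504	89602362	858	DEL	INTRON=8/12,STRAND=1	FUT8
sv_20057	12	1754287	1754351	64	DEL	INTRON=11/31,STRAND=-1	RPTOR
sv_09701	5	79832933	79833069	136	DEL	INTRON=2/2,STRAND=-1	CHST11
sv_17909	10	14546142	14546464	322	DEL	INTRON=2/10,STRAND=1	PSEN2
sv_06478	3	117923399	117923537	138	DUP	INTRON=11/21,STRAND=1	PUM2
sv_15424	8	124327820	124327887	67	DEL	INTRON=1/15,STRAND=1	UNC5C
sv_14140	8	14819672	14819672	57	INS	INTRON=4/39,STRAND=1	SLIT2
sv_00838	1	53380201	53380503	302	DEL	INTRON=18/26,STRAND=-1	CEP162
sv_02630	1	246244121	246244330	209	DEL	INTRON=2/50,STRAND=-1	ABCA1
sv_22719	13	137104024	137104685	661	DEL	INTRON=12/20,STRAND=1	ADCY5
sv_03472	2	25622346	25622540	194	DEL	INTRON=1/10,STRAND=1	SLC1A2
sv_16374	9	39266560	39266881	321	DEL	INTRON=4/9,STRAND=-1	BTG4
sv_12463	7	14235194	14235332	138	DEL	INTRON=11/16,STRAND=1	RNF144B
sv_12468	7	14574297	14574588	291	DEL	INTRON=16/16,STRAND=1	RNF144B
sv_20094	12	5242599	5242945	346	DEL	INTRON=1/19,STRAND=1	RNF157
sv_02955	1	268335021	268335100	79	DEL	INTRON=1/13,STRAND=-1	ENG
sv_21044	12	59897867	59897867	51	INS	INTRON=1/10,STRAND=1	ALDH3A1
sv_13020	7	53755609	53755689	80	DUP	INTRON=20/23,STRAND=-1	ALDH1L1
sv_11808	6	149630210	149630516	306	DEL	INTRON=9/11,STRAND=-1	ATG4C
sv_27208	15	133594044	133594148	104	DEL	INTRON=13/26,STRAND=1	INPP5D
sv_14236	8	19500083	19500145	62	DEL	INTRON=6/12,STRAND=1	SLC34A2
sv_12131	6	166363129	166363766	637	DEL	INTRON=2/10,STRAND=1	EIF2B3
sv_22679	13	133322069	133322328	259	DEL	INTRON=9/21,STRAND=-1	PAK2
sv_03313	2	16611778	16612068	290	DEL	INTRON=1/10,STRAND=-1	CRY2
sv_11779	6	148337406	148337584	178	DUP	INTRON=7/8,STRAND=-1	ROR1
sv_11783	6	148486408	148486821	413	DEL	INTRON=2/8,STRAND=-1	ROR1
sv_10737	6	44037692	44037873	181	DEL	INTRON=13/29,STRAND=1	GPI
sv_01505	1	119812278	119812356	78	DEL	INTRON=1/12,STRAND=1	LEO1
sv_00508	1	29660305	29660787	482	DEL	INTRON=1/13,STRAND=1	SGK1
sv_29831	18	5418190	5419615	1425	DEL	INTRON=2/9,STRAND=-1	GALNTL5
sv_29632	17	52827801	52828714	913	DUP	INTRON=3/11,STRAND=-1	NFATC2
sv_25217	14	134421991	134422184	193	DEL	INTRON=3/11,STRAND=-1	CTBP2
sv_13418	7	93027107	93027168	61	DEL	INTRON=11/15,STRAND=1	GALNT16
sv_29956	18	13806603	13806603	58	INS	INTRON=1/42,STRAND=-1	NUP205
sv_28139	16	28242760	28242907	147	DEL	INTRON=19/23,STRAND=1	NNT
sv_08616	5	9349445	9349445	65	INS	INTRON=4/8,STRAND=-1	TOMM22
sv_27216	15	134115973	134116307	334	DEL	INTRON=4/8,STRAND=-1	HJURP
sv_22572	13	121939152	121939152	59	INS	INTRON=3/29,STRAND=-1	ABCC5
sv_02568	1	241731580	241731635	55	DEL	INTRON=3/6,STRAND=1	STX17
sv_29840	18	6193747	6194358	611	DEL	INTRON=1/15,STRAND=-1	ABCB8
sv_13477	7	97732176	97732450	274	DEL	INTRON=3/3,STRAND=-1	NPC2
sv_22791	13	146185493	146185553	60	DEL	INTRON=2/15,STRAND=-1	ATP6V1A
sv_24925	14	115794719	115795323	604	DEL	INTRON=2/28,STRAND=1	SORCS3
sv_20679	12	39646645	39646954	309	DEL	DISTANCE=1644,STRAND=1	CCL5
sv_04865	2	143537750	143538086	336	DEL	DISTANCE=2769,STRAND=1	RNF14
sv_04626	2	129802694	129802969	275	DEL	DISTANCE=4352,STRAND=1	LMNB1
sv_29412	17	38646660	38646795	135	DEL	DISTANCE=2728,STRAND=-1	EIF6
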