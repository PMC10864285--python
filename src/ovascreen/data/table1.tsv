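gene_id	gene_symbol	human_ortholog	mouse_ortholog	stock_id	mvd1	mata	no_stage14	tub_gal4
CG10050	Dtwd2	DTWD2	Dtwd2	GL01481	505, 0 NDJ	119, 1 NDJ
CG10336	CG10336	TIPIN	Tipin	HMJ22595	610, 0 NDJ	55, 0 NDJ
CG10336	CG10336	TIPIN	Tipin	GLC01611	STERILE	6, 0 NDJ		Viable
CG10344	CG10344	ZDHHC2	Zdhhc25	HMS00197	318, 0 NDJ	119, 8 NDJ
CG10635	Pfdn4	PFDN4	Pfdn4	HMC06544	526, 1 NDJ	42, 2 NDJ		Viable
CG10981	dgrn	RNF4	Rnf4	GL00588	565, 5 NDJ	903, 3 NDJ
CG11133	BoYb	DDX46	Ddx46	HMJ23886	STERILE	STERILE		Viable
CG11188	Aatf	AATF	Aatf	HMC04594	STERILE	STERILE
CG11660	RIOK1	RIOK1	Riok1	GL00195	175, 0 NDJ	STERILE	Mata	Lethal
CG11660	RIOK1	RIOK1	Riok1	HMC04524	STERILE	STERILE
CG11674	CG11674	DKK4	Dkk1	HMS04336	819, 2 NDJ	50, 0 NDJ
CG11985	Sf3b5	SF3B5	Sf3b5	HMS00097	STERILE	32, 0 NDJ
CG12018	PolD2	POLD2	Pold2	HMC06042	694, 0 NDJ	95, 1 NDJ		Viable
CG12077	PIG-C	PIGC	Pigc	HMC06127	354, 0 NDJ	99, 0 NDJ
CG12179	Alms1a	notfound	notfound	HMJ30289	ND	16, 0 NDJ
CG12259	CG12259	FAM50A	Fam50a	HMJ23711	534, 22 NDJ	386, 2 NDJ		Viable
CG1239	CG1239	MEPCE	Mepce	HMS02605	STERILE	52, 0 NDJ		Lethal
CG1239	CG1239	MEPCE	Mepce	HMS02507	212, 0 NDJ	30, 0 NDJ
CG1239	CG1239	MEPCE	Mepce	HMS02738	STERILE	STERILE
CG1239	CG1239	MEPCE	Mepce	HMC02896	STERILE	96, 0 NDJ		Lethal
CG13096	CG13096	RSL1D1	Rsl1d1	HMS00206	STERILE	41, 0 NDJ
CG13690	CG13690	RNASEH2A	Rnaseh2a	HMC03555	43, 0 NDJ	STERILE		Viable
CG13741	Boot	notfound	notfound	GL00570	STERILE	76, 1 NDJ		Lethal
CG13773	Polr1F	TWISTNB	Twistnb	HMC05572	STERILE	167, 0 NDJ
CG14174	CG14174	NEPRO	Nepro	HMJ30042	STERILE	STERILE	MVD1, Mata	Lethal
CG14230	CG14230	NOL8	Nol8	GLC01782	257, 1 NDJ	STERILE	Mata	Lethal
CG14303	qin	TDRD5	Tdrd5	GL01398	52, 0 NDJ	468, 0 NDJ		Viable
CG14931	CG14931	notfound	notfound	GL00727	353, 0 NDJ	454, 4 NDJ
CG14962	Asciz	ATMIN	Atmin	HMJ21116	292, 3 NDJ	397, 0 NDJ
CG15220	RPA3	RPA3	Rpa3	HMJ24068	STERILE	STERILE	MVD1	Lethal
CG15436	Paris	ZNF763	Zscan26	HMC04637	485, 5 NDJ	175, 0 NDJ
CG15863	Pdrg1	PDRG1	Pdrg1	HMC05965	STERILE	131, 0 NDJ		Viable
CG1677	CG1677	ZC3H18	Zc3h18	HMC04042	STERILE	STERILE		Viable
CG16838	elg1	CRLF3	Crlf3	HMC03187	STERILE	STERILE	Mata	Leaky
CG16838	elg1	CRLF3	Crlf3	HMJ30117	59, 0 NDJ	STERILE	Mata	Leaky
CG16892	Aladin	AAAS	Aaas	HMC03342	541, 1 NDJ	39, 0 NDJ
CG17233	CG17233	CCDC82	Ccdc82	HMJ22836	462, 0 NDJ	24, 0 NDJ
CG17361	CG17361	notfound	notfound	HMC04903	418, 0 NDJ	STERILE		Viable
CG17658	CG17658	CHAT	notfound	GL01020	396, 1 NDJ	284, 3 NDJ
CG17829	Hinfp	HINFP	Hinfp	GL01162	352, 8 NDJ	229, 4 NDJ		Viable
CG18586 /// CG5568	CG5568	ACSBG2	Acsbg2	HMJ23127	ND	99, 0 NDJ
CG18787 /// CG18789	CG18787	NUP42	Nupl2	HMC03818	STERILE	19, 0 NDJ	MVD1	Viable
CG18787 /// CG18789	CG18787	NUP42	Nupl2	HMC04063	466, 1 NDJ	55, 0 NDJ		Viable
CG2051	Hat1	HAT1	Hat1	HMS01210	STERILE	STERILE	MVD1
CG2199	CG2199	ZFP92	Zfp92	HMJ30228	STERILE	136, 0 NDJ
CG2924	CG2924	UBE2Q1	Ube2dnl2	GLC01774	428, 1 NDJ	26, 1 NDJ
CG30020	CG30020	ZFP92	Zfp92	HMJ22046	STERILE	289, 0 NDJ	MVD1	Viable
CG30467	CG30467	SAAL1	Saa4	HMC04317	ND	227, 2 NDJ
CG31998	CG31998	PRRT3	Prrt3	GL01256	155, 0 NDJ	27, 0 NDJ
CG32344	CG32344	DDX54	Ddx54	HMJ23354	STERILE	STERILE		Lethal
CG33217	CG33217	PELP1	Pelp1	GL01509	STERILE	STERILE	Mata	Lethal, F1
CG33217	CG33217	PELP1	Pelp1	HMS02699	STERILE	STERILE		Lethal, F1
CG33228	CG33228	RBM28	Rbm28	HMC04060	539, 0 NDJ	119, 1 NDJ
CG3407	CG3407	ZNF692	E4f1	HMC04955	409, 1 NDJ	400, 15 NDJ
CG34261	CG34261	OARD1	Oard1	HMC06638	386, 12 NDJ	177, 0 NDJ
CG3430	CG3430	MCMBP	Mcmbp	HMC06551	586, 2 NDJ	226, 18 NDJ	Mata	Lethal
CG3430	CG3430	MCMBP	Mcmbp	GL01184	42, 0 NDJ	STERILE	Mata	Lethal
CG3680	HIPP1	CDYL2	Cdyl2	HMC05150	536, 0 NDJ	159, 5 NDJ
CG40042	Tim23	TIMM23	Timm23	HMC06553	STERILE	STERILE		Lethal
CG42232	CG42232	MAP1A	Mki67	GL01022	STERILE	720, 3 NDJ
CG42307 /// mus312	mus312	SLX4	Slx4	HMS00381	STERILE	272, 0 NDJ		Lethal
CG42388	Nost	NOSTRIN	Nostrin	GL01145	ND	STERILE
CG4554	CG4554	UTP20	Utp20	HMC03176	196, 0 NDJ	STERILE		Lethal
CG4730	CG4730	ZNF362	Zfp362	HMC05139	524, 0 NDJ	260, 4 NDJ
CG4771	vret	TDRD1	Snd1	GL00653	459, 1 NDJ	59, 0 NDJ
CG4849	CG4849	EFTUD2	Eftud2	HMS01994	592, 2 NDJ	90, 0 NDJ
CG4857	tyf	notfound	notfound	HMS05700	629, 6 NDJ	718, 2 NDJ
CG4936	CG4936	ZSCAN4	Zscan4c	HMC05569	STERILE	39, 0 NDJ
CG4951	CG4951	notfound	notfound	GL01154	STERILE	STERILE		Viable
CG4973///DpseGA18564	mdlc	RNF113A	Rnf113a2	HMS04472	STERILE	86, 0 NDJ
CG4980	BCAS2	BCAS2	Bcas2	HMJ22596	271, 3 NDJ	150, 0 NDJ
CG5131	CG5131	ATP23	Atp23	HMC06573	449, 0 NDJ	31, 0 NDJ
CG5235	CG5235	MOXD1	Moxd1	GL01241	591, 6 NDJ	95, 1 NDJ
CG5626	Tsen54	TSEN54	Tsen54	GL00247	247, 0 NDJ	54, 0 NDJ
CG5757	CG5757	CMPK2	Dtymk	HMJ23271	STERILE	8, 0 NDJ		Lethal
CG5877	CG5877	NRDE2	Nrde2	HMC03904	STERILE	233, 2 NDJ	MVD1	Viable
CG6227	Prp5	DDX46	Ddx46	HMJ24050	STERILE	80, 0 NDJ
CG6540	Nup35	NUP35	Nup35	HMC06300	304, 0 NDJ	STERILE	Mata	Lethal
CG6610	CG6610	LSM5	Lsm5	HMS04506	138, 0 NDJ	180, 3 NDJ
CG6693	CG6693	DNAJC9	Dnajc9	GL01534	231, 0 NDJ	438, 5 NDJ		Viable
CG6843	CG6843	CIR1	Cir1	HMC05138	ND	257, 12 NDJ		Viable
CG6937	CG6937	PABPN1L	Pabpn1l	HMC04778	455, 17 NDJ	540, 2 NDJ
CG6937	CG6937	PABPN1L	Pabpn1l	GL01252	STERILE	STERILE		Leaky
CG6951	CG6951	DCTD	Dctd	HMS03371	627, 1 NDJ	STERILE		Viable
CG6951	CG6951	DCTD	Dctd	HMS03380	154, 0 NDJ	50, 0 NDJ		Lethal
CG7033	CCT2	CCT2	Cct2	HMS01190	ND	STERILE		Lethal, F1
CG7156	CG7156	RPS6KL1	Rps6kl1	GL00155	643, 1 NDJ	367, 4 NDJ
CG7185	Cpsf6	CPSF7	Cpsf7	HMS00113	STERILE	STERILE		Lethal
CG7357	Odj	GFI1B	Zfp518b	HMJ23468	STERILE	621, 0 NDJ		Lethal
CG7357	Odj	GFI1B	Zfp518b	HMC05191	STERILE	265, 0 NDJ
CG7372	Phs	ZNF20	BC025920	HMC05211	434, 0 NDJ	77, 0 NDJ
CG7386	CG7386	ZNF668	Zfp668	HMC05188	460, 0 NDJ	82, 0 NDJ		Viable
CG7609	Wdr24	WDR24	Wdr24	HMJ23816	631, 1 NDJ	58, 0 NDJ
CG7730	CG7730	notfound	notfound	GL01109	53, 0 NDJ	37, 0 NDJ
CG7971	Srrm234	SRRM2	Srrm2	HMC03678	STERILE	STERILE		Lethal
CG7993	Non3	RPF2	Rpf2	HMS02628	STERILE	98, 0 NDJ		Viable
CG8116	TMEM216	TMEM80	Tmem80	HMJ21848	705, 2 NDJ	41, 0 NDJ
CG8142	CG8142	RFC4	Rfc4	HMJ02051	STERILE	116, 0 NDJ	MVD1	Viable
CG8142	CG8142	RFC4	Rfc4	GL00569	STERILE	STERILE		Lethal
CG8173	CG8173	PBK	Pbk	GL01801	156, 0 NDJ	21, 0 NDJ
CG8173	CG8173	PBK	Pbk	HMS05007	425, 0 NDJ	326, 3 NDJ
CG8232///Rcp	Rbbp5	PAN2	Pan2	GLC01808	421, 0 NDJ	101, 1 NDJ
CG8298	CG8298	GK3P	Gk2	GL00301	514, 1 NDJ	20, 0 NDJ
CG8435	CG8435	YJU2	Yju2	GL00696	STERILE	431, 0 NDJ		Viable
CG8435	CG8435	YJU2	Yju2	GL00696	STERILE	46, 0 NDJ
CG8728	CG8728	PMPCA	Pmpca	HMS00561	STERILE	STERILE
CG8915	CG8915	YTHDC2	Ythdc2	HMS00697	897, 10 NDJ	493, 1 NDJ		Viable
CG8950	CG8950	GTF3C3	Gtf3c3	HMC02421	526, 1 NDJ	271, 5 NDJ
CG8950	CG8950	GTF3C3	Gtf3c3	HMJ22532	325, 0 NDJ	297, 5 NDJ
CG9203	mh	SPRTN	Sprtn	GLC01597	ND	STERILE		Lethal
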