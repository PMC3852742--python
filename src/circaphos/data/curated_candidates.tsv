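entry	category	protein_description	site_sequence	gene_id	closest_human_relative	e_value	identity	accession	alters_hs_clock	rhythmic_mm
1	both	L-asparaginase-like	S(p)LGLLPGPTK	Ot13g02360	L-asparaginase	1e-35	34%	AAH35836.1	yes_both	yes
2	both	Armadillo/plakoglobin	AAS(p)AEIASDYVATPGGSR	Ot15g02430	Uridine-Cytidine Kinase 1-like	3e-20	32%	EAW75186.1	no	yes
3	both	PI-4-phosphate 5-kinase	LRSS(p)VANVTAFATEEPL	Ot02g07550	PI-4-phosphate 5-kinase	2e-06	23%	AAC50916.1	yes_both	yes
4	both	Ankyrin repeats protein	AMQRGSS(p)LLDLQSADGGTPAMSAAAHSYGDVLQYLIEK	Ot08g01070	Ankyrin repeat domain 17	2e-05	38%	AAH43394.1	yes_both	yes
5	both	unnamed protein product	ASTLNDST(p)ADDGNVVR	Ot07g03300	Ankyrin/Armadillo repeats protein	0.014	24%	EAX10893.1	no	no
6	both	unnamed protein product	EAFGDAS(p)DDDAFSPR	Ot14g01520	Poliovirus receptor-related 4	1.6	32%	BAG61075.1	yes_both	yes
7	both	unnamed protein product	ET(p1)KT(p2,3)LAELMS(p3)INMGA	Ot04g00360	RNF181	1.8	42%	CCQ43543.1	no	no
8	both	unnamed protein product	GGQEGS(p)PSKSLSSPK	Ot14g02110	N/A	N/A	N/A	N/A	unknown	unknown
9	both	unnamed protein product	ALEDES(p)PVAVVKEK	Ot01g02950	N/A	N/A	N/A	N/A	unknown	unknown
10	both	unnamed protein product	TKDAAEAS(p)DEDVVATR	Ot01g02280	N/A	N/A	N/A	N/A	unknown	unknown
11	tau_only	CDPK	SES(p)FAILTEAAK	Ot10g01030	Death-associated protein kinase 3	2e-37	31%	NP_001339.1	yes_both	yes
12	wt_only	Phox	AIS(p)PAPEER	Ot05g00090	Sorting nexin 1, phox domain	4e-13	22%	NP_003090.2	yes_both	yes
13	wt_only	Trehalose-phosphate synthase	PADGST(p)PESPPRR	Ot01g02410	H+ transporting ATPase	5.8	35%	EAW99791.1	yes_period	yes
14	neither	putative TAF6 RNA polymerase	GT(p)TPDDDIGDAAAAHAPNVAVAETHV	Ot13g00540	TAF6 RNA polymerase II	4e-65	34%	EAW76588.1	yes_both	yes
15	neither	unnamed protein product	APAGAKPGITLPSNPFAAKPAT(p)KATPAAK	Ot14g01370	Unknown protein	2e-38	40%	AAH53854.1	no	no
16	neither	unnamed protein product	FGIVDGS(p)ASTETPETFVK	Ot08g03890	Spondin 1	0.36	25%	AAH19825.1	yes_period	yes
17	neither	unnamed protein product	ALASDS(p)EDDERPR	Ot04g04920	Importin beta	1.1	38%	NP001263382.1	no	no
18	neither	unnamed protein product	TAS(p)PMTSPMASPSPAD	Ot17g01690	2,3-bisphosphoglycerate mutase	9.2	33%	BAD92281.1	yes_both	yes
19	neither	unnamed protein product	SAS(p)YDSLLGAVPASTFPRPIPLAEMVR	Ot15g00280	N/A	N/A	N/A	N/A	unknown	unknown
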