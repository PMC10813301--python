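# 39 independent pleiotropic loci between age at menarche (trait 1) and
# type-2-diabetes traits (trait 2) at cFDR < 0.05, transcribed from the
# published Taiwan Biobank cross-trait cFDR analysis. Numbers are kept in
# the printed typeset notation; blank leading fields continue the previous
# index SNP with an additional trait-2 phenotype row.
Chr	rs	Position (hg38)	Gene	p of Trait 1	Trait 2	p of Trait 2	cFDR
1	rs148500298	1.02 × 10^8	RP11-202K23.1	0.658659	FBG	5.25 × 10−6	0.040840737
1	rs3138105	1.58 × 10^8	CD1B, CD1C	0.475425	HbA1c	9.86 × 10−6	0.045925272
1	rs17042165	2.15 × 10^8	LOC124904510	0.00217096	HbA1c	4.61 × 10−6	0.007599174
2	rs780093	27,519,736	GCKR	0.320034	FBG	4.80 × 10−7	0.007515765
2	rs895636	44,961,214	AC012354.6	0.807344	FBG	1.67 × 10−7	0.003508871
2	rs1402837	1.69 × 10^8	G6PC2	0.280055	HbA1c	1.44 × 10−8	0.00028397
					FBG	1.32 × 10−13	1.82 × 10−8
2	rs116933981	1.69 × 10^8	LRP2	0.41804	FBG	8.63 × 10−7	0.012442801
3	rs3804766	51,393,226	RBM15B	0.208714	HbA1c	3.20 × 10−6	0.033487115
4	rs223461	1.03 × 10^8	LOC102723704, LOC124900743	0.192597	HbA1c	5.45 × 10−6	0.048127897
4	rs79196252	1.47 × 10^8	SLC10A7	0.0439132	FBG	8.66 × 10−7	0.010702327
5	rs248062	1.27 × 10^8	CTB-1I21.1	0.0326756	BFP	4.10 × 10−7	0.007739594
5	rs75170429	1.33 × 10^8	FSTL4	0.419274	HbA1c	2.51 × 10−6	0.019516832
6	rs2206734	20,694,653	CDKAL1	0.712727	HbA1c	1.94 × 10−14	6.49 × 10−10
					FBG	3.05 × 10−7	0.006010452
6	rs9376090	1.35 × 10^8	HBS1L	0.695327	HbA1c	7.17 × 10−6	0.041947507
7	rs10244051	15,024,208	GTF3AP5	0.776841	FBG	8.57 × 10−7	0.012993208
7	rs16881016	44,171,808	GCK, LOC105375257	0.480132	HbA1c	4.52 × 10−10	8.01 × 10−6
					FBG	2.01 × 10−11	2.31 × 10−6
7	rs1799884	44,189,469	GCK	0.264629	FBG	3.12 × 10−6	0.029224933
7	rs6975024	44,192,287	GCK	0.601593	HbA1c	2.22 × 10−7	0.002111339
7	rs2233580	1.28 × 10^8	PAX4	0.403983	T2DM	5.07 × 10−10	9.90 × 10−5
					HbA1c	6.18 × 10−10	1.51 × 10−5
					FBG	2.70 × 10−7	0.005270602
7	rs6943771	1.4 × 10^8	PARP12	0.995326	FBG	4.37 × 10−6	0.038811336
8	rs3802177	1.17 × 10^8	SLC30A8, LOC105375716	0.889634	HbA1c	8.07 × 10−12	1.67 × 10−7
					FBG	7.81 × 10−12	1.62 × 10−6
9	rs10965250	22,133,285	CDKN2B-AS1	0.236788	HbA1c	8.65 × 10−13	1.02 × 10−7
					FBG	3.00 × 10−11	3.54 × 10−6
9	rs1050700	1.33 × 10^8	TSC1	0.487359	HbA1c	1.16 × 10−5	0.049462307
10	rs12221133	12,211,598	CDC123	0.45323	HbA1c	1.44 × 10−6	0.010460355
10	rs151268010	16,675,558	RSU1	0.0122221	BFP	3.57 × 10−6	0.027178562
10	rs75631171	92,449,649	IDE	0.190513	T2DM	2.55 × 10−7	0.024501519
10	rs1111875	92,703,125	Y_RNA	0.664192	T2DM	2.59 × 10−7	0.027071426
10	rs10786156	94,254,865	PLCE1	0.332509	BFP	1.02 × 10−8	0.00165048
11	rs60808706	2,836,003	KCNQ1	0.589924	HbA1c	3.38 × 10−12	9.49 × 10−8
					FBG	6.33 × 10−9	0.000221717
11	rs10466351	92,964,815	LOC124902733	0.44799	FBG	1.25 × 10−10	6.76 × 10−6
11	rs10830963	92,975,544	MTNR1B	0.526219	HbA1c	6.32 × 10−7	0.005298336
17	rs761772	78,125,997	TMC6	0.429945	HbA1c	4.79 × 10−12	1.42 × 10−7
17	rs73357173	82,670,096	RAB40B/MIR4525	0.0342794	HbA1c	2.89 × 10−6	0.019044672
17	rs2250754	82,703,440	LOC124904093	0.0102342	HbA1c	1.73 × 10−6	0.01124699
17	rs1046896	82,727,657	FN3KRP	0.382707	HbA1c	3.68 × 10−54	6.84 × 10−49
17	rs3785519	82,937,832	TBCD	0.177841	HbA1c	2.08 × 10−8	0.000467929
17	rs58431774	83,000,587	B3GNTL1	0.742557	HbA1c	7.61 × 10−15	2.95 × 10−10
21	rs7510550	36,629,993	AP000696.2	0.515658	FBG	7.92 × 10−7	0.01085386
22	rs146847831	48,773,800	FAM19A5	0.106661	FBG	1.42 × 10−6	0.019983018
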