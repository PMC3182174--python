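accession	protein	effect	p_cl_kl	rs_cl_a	rs_kl	p_ch_kh	rs_ch_a	rs_kh	p_cl_ch	rs_cl_b	rs_ch_b
XP_392490	Retinoid- and fatty-acid binding protein	G	0.151	35	20	0.222	21	34	0.008	40	15
XP_394991	Tubulin alpha-6 chain	G	1.000	27	28	0.222	21	34	0.008	40	15
NP_001011563	Juvenile hormone esterase	G	0.421	32	23	0.310	22	33	0.008	40	15
XP_001120641	Pericardin	G	0.222	21	34	0.841	29	26	0.008	15	40
XP_624700	Histone 2 A	G	1.000	28	27	1.000	28	27	0.008	15	40
XP_001120934	Histone 2 A	G	1.000	28	27	1.000	28	27	0.008	15	40
XP_001119899	Histone 2 A	G	1.000	28	27	1.000	28	27	0.008	15	40
XP_001120346	Histone 2 A	G	1.000	28	27	1.000	28	27	0.008	15	40
XP_001120186	Histone 2 A	G	1.000	28	27	1.000	28	27	0.008	15	40
XP_623470	Tropomyosin 1, isoform B isoform 2	G	0.690	30	25	0.690	30	25	0.016	16	39
XP_624943	Ribosomal protein S7, isoform A	G	0.310	33	22	0.841	26	29	0.016	39	16
XP_393281	Paramyosin, isoform A	G	0.421	23	32	1.000	28	27	0.016	16	39
XP_392125	Tropomyosin 1, isoform D isoform 1	G	0.690	30	25	1.000	28	27	0.016	16	39
NP_001011651	Troponin C type IIIa	G	0.690	25	30	0.690	30	25	0.032	17	38
XP_623046	Tropomyosin 1, isoform D	G	0.548	31	24	0.841	26	29	0.032	17	38
XP_624408	Oxidoreductase	G	0.151	35	20	1.000	28	27	0.032	38	17
XP_396922	Amine oxidase, isoform 1	G	0.151	35	20	0.421	23	32	0.056	18	37
XP_392970	Lon protease, isoform A	G	0.690	30	25	0.690	25	30	0.056	37	18
XP_623298	Tropomyosin 1, isoform A	G	1.000	27	28	0.841	29	26	0.056	18	37
NP_001035348	Troponin T	G	0.841	29	26	1.000	27	28	0.056	18	37
XP_623143	Pugilist, isoform A isoform 2	G	0.548	24	31	1.000	27	28	0.095	36	19
XP_623070	Pugilist, isoform A isoform 1	G	0.548	24	31	1.000	27	28	0.095	36	19
XP_624353	Aldo-keto reductase, isoform A isoform 1	T	0.421	23	32	0.008	15	40	0.310	22	33
XP_391994	Aconitase	T	0.841	29	26	0.016	39	16	0.690	30	25
XP_392997	Glutathione S-transferase 1-1 (GST class-theta)	T	0.421	23	32	0.032	17	38	0.690	25	30
XP_391843	Yippee interacting protein 2	T	0.222	21	34	0.056	37	18	0.548	31	24
XP_392722	Tat-binding protein-1	T	0.222	34	21	0.056	37	18	0.421	23	32
XP_001120471	3-hydroxyacyl-CoA dehydrogenase type II	T	0.310	22	33	0.095	36	19	0.690	25	30
XP_394469	Tubulin at 60D	T	0.008	40	15	0.310	33	22	0.421	32	23
XP_623673	Isocitrate dehydrogenase, isoform C isoform 2	T	0.016	39	16	0.151	20	35	0.222	34	21
XP_001122661	Glutamate oxaloacetate transaminase 1, isoform A	T	0.032	17	38	0.421	32	23	0.421	23	32
XP_394471	Tubulin, beta, 2	T	0.032	38	17	0.841	26	29	0.841	26	29
XP_624112	Vacuolar H+-ATPase 55 kD B subunit, isoform B	T	0.056	18	37	0.310	22	33	0.421	32	23
XP_393806	3-hydroxyacyl-CoA dehydrogenase, isoform A	T	0.056	18	37	0.421	23	32	0.690	30	25
XP_625027	Elongation factor 1-beta (EF-1-beta)	T	0.095	36	19	0.690	25	30	0.690	30	25
NP_001035323	Cytochrome P450 monooxygenase	G&T	0.056	37	18	0.008	15	40	0.008	40	15
XP_392479	14-3-3, isoform C isoform 1	G&T	0.421	32	23	0.032	17	38	0.008	40	15
XP_001122876	Hypothetical protein	G&T	0.841	26	29	0.095	36	19	0.008	15	40
XP_394645	HSC70-interacting protein, isoform A isoform 1	G&T	0.056	37	18	0.151	20	35	0.008	40	15
XP_624156	ATP synthase, isoform A	G&T	0.095	19	36	0.151	35	20	0.008	15	40
XP_395976	CG33257-PA	G&T	0.095	19	36	0.310	33	22	0.008	15	40
XP_001122872	Apidermin 2	G&T	0.032	17	38	0.016	39	16	0.016	16	39
XP_624041	Hexamerin 110 (Larval serum protein 2)	G&T	0.016	39	16	0.548	31	24	0.016	39	16
XP_392679	Dihydrolipoamide S-succinyltransferase	G&T	0.222	21	34	0.056	37	18	0.032	17	38
NP_001011578	Vitellogenin	G&T	0.095	36	19	0.095	36	19	0.032	38	17
NP_001011572	Transferrin	G&T	0.095	19	36	0.095	19	36	0.032	38	17
XP_397201	CG6459-PA	G&T	1.000	28	27	0.095	19	36	0.032	38	17
XP_392313	Tubulin at 56D, isoform B	G&T	0.032	38	17	0.310	33	22	0.032	38	17
XP_624781	60S acidic ribosomal protein P1 (RP21C)	G&T	0.548	24	31	0.008	15	40	0.095	36	19
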