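subset	accession	gene	description	n_ref	n_cmp	expected_rsc
ref_unique	Q860I7	HLA-B	MHC class I antigen	75	0	-54.5
ref_unique	B7ZLH8	EVPL	EVPL protein	52	0	-38.1
ref_unique	I6NXG5	HLA-C	MHC class I antigen	42	0	-30.9
ref_unique	P20592	MX2	Interferon-induced GTP-binding protein Mx2	28	0	-20.9
ref_unique	H0Y3C5	HCK	Tyrosine-protein kinase HCK	19	0	-14.5
ref_unique	B0QZ43	ERLIN1	Erlin-1 (Fragment)	19	0	-14.5
ref_unique	P02549	SPTA1	Spectrin alpha chain, erythrocytic 1	16	0	-12.3
ref_unique	Q8IVF2	AHNAK2	Protein AHNAK2	15	0	-11.6
ref_unique	O60449	LY75	Lymphocyte antigen 75	14	0	-10.9
ref_unique	Q9ULV0	MYO5B	Unconventional myosin-Vb	14	0	-10.9
cmp_unique	P23378	GLDC	Glycine dehydrogenase [decarboxylating], mitochondrial	0	21	19.9
cmp_unique	P21266	GSTM3	Glutathione S-transferase Mu 3	0	21	19.9
cmp_unique	Q56FN6	HLA-DRB1	MHC class II antigen	0	16	15.5
cmp_unique	Q13085	ACACA	Acetyl-CoA carboxylase 1	0	13	12.8
cmp_unique	Q52NV4	HRS	Histidyl-tRNA synthetase	0	12	11.9
cmp_unique	C9J837	RAB3GAP1	Rab3 GTPase-activating protein catalytic subunit	0	11	11.0
cmp_unique	P42771	CDKN2A	Cyclin-dependent kinase inhibitor 2A	0	9	9.2
cmp_unique	B4DF41	MSH6	DNA mismatch repair protein Msh6	0	9	9.2
cmp_unique	B3KMS0	NACAPD2	Condensin complex subunit 1	0	9	9.2
cmp_unique	D6RE83	UCHL1	Ubiquitin carboxyl-terminal hydrolase isozyme L1	0	8	8.3
common_enriched	Q99715	COL12A1	Collagen alpha-1 (XII) chain	1	23	12.1
common_enriched	P08243	ASNS	Asparagine synthetase [glutamine-hydrolyzing]	1	20	10.6
common_enriched	P37268	FDFT1	Squalene synthase	1	12	6.6
common_enriched	O60701	UGDH	UDP-glucose 6-dehydrogenase	3	23	6.4
common_enriched	Q96C36	PYCR2	Pyrroline-5-carboxylate reductase 2	4	26	5.8
common_enriched	Q9UKF6	CPSF3	Cleavage and polyadenylation specificity factor subunit 3	1	10	5.6
common_enriched	B4DHQ3	PSAT	Phosphoserine aminotransferase	1	10	5.6
common_enriched	Q8NFF5	FLAD1	FAD synthase	3	19	5.3
common_enriched	O15230	LAMA5	Laminin subunit alpha-5	1	9	5.1
common_enriched	Q6UX53	METTL7B	Methyltransferase-like protein 7B	1	9	5.1
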