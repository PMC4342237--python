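strain_id	display_name	lifestyle	growth_rate	pathogenicity	pah_metabolism	genome_size	gc	gene_count	cog_count
M_smegmatis_MC2-155	Mycobacterium smegmatis MC2 155	FL	fast	non-pathogenic	non-degrading	6988209	0.67	6941	4796
M_vanbaalenii_PYR-1	Mycobacterium vanbaalenii PYR-1	FL	fast	non-pathogenic	degrading	6491865	0.68	6047	4186
Mycobacterium_sp_KMS	Mycobacterium sp. KMS	FL	fast	non-pathogenic	degrading	6256079	0.68	6089	4135
Mycobacterium_sp_JLS	Mycobacterium sp. JLS	FL	fast	non-pathogenic	degrading	6048425	0.68	5855	4148
M_gilvum_PYR-GCK	Mycobacterium gilvum PYR-GCK	FL	fast	non-pathogenic	degrading	5982829	0.68	5683	3901
Mycobacterium_sp_MCS	Mycobacterium sp. MCS	FL	fast	non-pathogenic	degrading	5920523	0.68	5704	3955
M_gilvum_Spyr1	Mycobacterium gilvum Spyr1	FL	fast	non-pathogenic	degrading	5783292	0.68	5434	4038
Mycobacterium_sp_JDM601	Mycobacterium sp. JDM601	FHA	slow	pathogenic	non-degrading	4643668	0.68	4398	3162
M_marinum_M	Mycobacterium marinum M, ATCC BAA-535	FHA	slow	pathogenic	non-degrading	6660144	0.66	5501	3717
M_ulcerans_Agy99	Mycobacterium ulcerans Agy99	FHA	slow	pathogenic	non-degrading	5805761	0.65	4306	2853
M_avium_104	Mycobacterium avium 104	FHA	slow	pathogenic	non-degrading	5475491	0.69	5305	3504
M_abscessus_CIP-104536	Mycobacterium abscessus CIP 104536	FHA	fast	pathogenic	non-degrading	5090491	0.64	4991	3301
M_avium_paratuberculosis_K-10	Mycobacterium avium subsp. paratuberculosis K-10	FHA	slow	pathogenic	non-degrading	4829781	0.69	4415	3188
M_canettii_CIPT-140010059	Mycobacterium canettii CIPT 140010059	FHA	slow	pathogenic	non-degrading	4482059	0.66	3909	2949
M_tuberculosis_F11	Mycobacterium tuberculosis F11 (ExPEC)	FHA	slow	pathogenic	non-degrading	4424435	0.66	4019	2791
M_tuberculosis_H37Ra	Mycobacterium tuberculosis H37Ra	FHA	slow	pathogenic	non-degrading	4419977	0.66	4099	2811
M_tuberculosis_H37Rv	Mycobacterium tuberculosis H37Rv (lab strain)	FHA	slow	pathogenic	non-degrading	4411532	0.66	4062	2807
M_tuberculosis_CCDC5180	Mycobacterium tuberculosis CCDC5180	FHA	slow	pathogenic	non-degrading	4405981	0.66	3639	2836
M_tuberculosis_CDC1551	Mycobacterium tuberculosis CDC1551	FHA	slow	pathogenic	non-degrading	4403706	0.66	4300	2716
M_tuberculosis_CCDC5079	Mycobacterium tuberculosis CCDC5079	FHA	slow	pathogenic	non-degrading	4398812	0.66	3695	2875
M_tuberculosis_KZN-1435	Mycobacterium tuberculosis KZN 1435 (MDR)	FHA	slow	pathogenic	non-degrading	4398250	0.66	4107	2799
M_africanum_GM041182	Mycobacterium africanum GM041182	FHA	slow	pathogenic	non-degrading	4389314	0.66	3880	2896
M_bovis_BCG_Pasteur-1173P2	Mycobacterium bovis BCG Pasteur 1173P2	FHA	slow	pathogenic	non-degrading	4374522	0.66	4048	2783
M_bovis_BCG_Tokyo-172	Mycobacterium bovis BCG Tokyo 172	FHA	slow	pathogenic	non-degrading	4371711	0.66	3996	2776
M_bovis_AF2122-97	Mycobacterium bovis AF2122/97	FHA	slow	pathogenic	non-degrading	4345492	0.66	4014	2760
M_leprae_TN	Mycobacterium leprae TN	OI	slow	pathogenic	non-degrading	3268203	0.58	2750	1175
M_leprae_Br4923	Mycobacterium leprae Br4923	OI	slow	pathogenic	non-degrading	3268071	0.58	1654	1173
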