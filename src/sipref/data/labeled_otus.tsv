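otu_id	best_hit	phylum	compartment	phase	heavy_ra_pct	community_ra_pct	trophic_class
OTU_4	Scytonema hyalinum ACT700	Cyanobacteria	BSC	RP	1.08	1.07	fixer
OTU_5	Scytonema hyalinum ATE704	Cyanobacteria	BSC	RP	1.40	1.14	fixer
OTU_12	Oscillatoriales cyanobacterium HS041.1	Cyanobacteria	BSC	RP	0.52	1.32	fixer
OTU_35	Pseudonocardia sp.	Actinobacteria	BSC	RP	3.02	2.19	fixer
OTU_3	Microvirga aerilata	Proteobacteria	US	RP	5.93	4.91	transformer
OTU_6	Pseudarthrobacter oxydans	Actinobacteria	US	RP	2.11	1.96	transformer
OTU_8	Rubellimicrobium sp.	Proteobacteria	US	RP	1.35	1.03	transformer
OTU_21	Noviherbaspirillum sp.	Proteobacteria	US	RP	1.32	1.28	fixer
OTU_25	Massilia agri	Proteobacteria	US	RP	1.25	1.02	transformer
OTU_26	Mesorhizobium sp.	Proteobacteria	US	RP	1.25	1.06	fixer
OTU_46	Nocardioides mesophilus	Actinobacteria	US	RP	1.09	1.15	transformer
OTU_2	Blastococcus mobilis	Actinobacteria	BSC	SHP	9.02	5.67	fixer
OTU_14	Geodermatophilus sp.	Actinobacteria	BSC	SHP	2.38	1.86	fixer
OTU_15	Modestobacter altitudinis	Actinobacteria	BSC	SHP	3.65	2.09	fixer
OTU_16	Actinomycetales bacterium	Actinobacteria	BSC	SHP	2.05	1.07	transformer
OTU_2	Blastococcus mobilis	Actinobacteria	US	SHP	7.68	6.88	fixer
OTU_14	Geodermatophilus sp.	Actinobacteria	US	SHP	1.93	1.34	fixer
OTU_15	Modestobacter altitudinis	Actinobacteria	US	SHP	6.06	5.48	fixer
OTU_16	Actinomycetales bacterium	Actinobacteria	US	SHP	3.19	2.65	transformer
OTU_22	Actinoplanes digitatis	Actinobacteria	US	SHP	2.13	2.06	transformer
OTU_35	Pseudonocardia sp.	Actinobacteria	US	SHP	1.97	1.72	fixer
OTU_46	Nocardioides mesophilus	Actinobacteria	US	SHP	1.42	1.58	transformer
OTU_114	Uncultured Solirubrobacter sp.	Actinobacteria	US	SHP	2.12	1.62	fixer
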