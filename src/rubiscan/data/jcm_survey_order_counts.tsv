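phylum	order	strains	IA	IB	IC	IE	I_THERMUS	II	h2_oxidation	sulfur_species_oxidation	microaerophilic	aerobic	sulfur_species_reduction	nitrate_reduction	photosystem
Actinomycetota	Acidimicrobiales	1	0	0	1	0	0	0	0	0	0	1	1	0	0
Actinomycetota	Actinomycetales	1	0	0	0	0	0	1	0	0	1	1	1	1	0
Actinomycetota	Micromonosporales	1	1	0	0	0	0	0	0	0	1	0	0	1	0
Actinomycetota	Mycobacteriales	7	0	0	0	7	0	0	7	1	7	0	0	4	0
Actinomycetota	Propionibacteriales	7	0	0	0	5	0	2	0	0	7	6	0	1	0
Actinomycetota	Pseudonocardiales	7	0	0	0	7	0	0	3	0	7	7	0	4	0
Actinomycetota	Solirubrobacterales	2	0	0	0	2	0	0	2	0	2	2	0	1	0
Actinomycetota	Streptosporangiales	32	0	0	0	32	0	0	21	2	26	32	0	22	0
Bacillota	Alicyclobacillales	1	0	0	0	1	0	0	0	1	1	0	1	0	0
Deinococcota	Thermales	7	0	0	0	0	7	0	1	4	0	7	7	4	0
Pseudomonadota	Acetobacterales	3	0	0	3	0	0	0	0	1	3	3	0	1	1
Pseudomonadota	Burkholderiales	20	0	0	18	0	0	2	4	6	17	18	1	8	1
Pseudomonadota	Hyphomicrobiales	13	0	0	13	0	0	0	2	3	13	13	1	3	5
Pseudomonadota	Lysobacterales	2	0	0	2	0	0	0	1	1	2	2	0	0	0
Pseudomonadota	Methylococcales	1	1	0	0	0	0	0	0	1	1	1	0	0	0
Pseudomonadota	Nevskiales	1	0	0	1	0	0	0	1	0	1	1	1	0	0
Pseudomonadota	Nitrosomonadales	2	0	0	2	0	0	0	2	1	2	2	2	2	0
Pseudomonadota	Rhodobacterales	16	5	0	9	0	0	3	8	15	14	15	15	11	2
Pseudomonadota	Rhodocyclales	3	1	0	2	0	0	0	2	2	3	3	0	3	0
Pseudomonadota	Rhodospirillales	6	2	0	3	0	0	1	5	6	6	6	0	5	2
Pseudomonadota	Sphingomonadales	1	0	0	1	0	0	0	0	0	1	1	0	0	1
Pseudomonadota	Steroidobacterales	3	0	0	3	0	0	0	1	0	1	3	0	2	0
Pseudomonadota	Thiotrichales	2	1	0	0	0	0	1	2	2	2	2	2	0	0
Pseudomonadota	Vibrionales	5	3	1	0	0	0	0	1	0	5	5	0	4	0
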