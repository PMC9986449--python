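species	n_nbs	n_genes_total	genome_size_mb	ploidy
Nymphaea colorata	123	24059	409	Diploid
Beta vulgaris	138	24255	515.8	Diploid
Manihot esculenta	299	32805	620.1	Hexaploid
Gossypium hirsutum	493	75376	2764.8	Tetraploid
Spirodela polyrhiza	28	19623	428	Haploid
Linum usitatissimum	132	43471	304.5	Diploid
Vitis vinifera	321	31845	486	Tetraploid
Arabidopsis thaliana	138	27655	115.6	Diploid
Amborella trichopoda	51	26846	685	Haploid
Brassica napus	304	85147	840	Tetraploid
Prunus persica	316	26873	219.6	Diploid
Trifolium pratense	259	39948	420	Tetraploid
Oryza sativa	143	42189	364.3	Diploid
Setaria viridis	245	38334	382.1	Diploid
Sesamum indicum	115	27147	410.3	Haploid
Miscanthus sinensis	478	67789	2007.04	Diploid
Sorghum bicolor	244	34129	687	Diploid
Helianthus annus	258	52243	3427.2	Diploid
Saccharum hybrid R570	60	25316	407.36	Aneuploid
Saccharum spontaneum	468	83825	2990.08	Octoploid
Saccharum officinarum	741	117927	6481.92	Octoploid
Saccharum hybrid SP80-3280	597	47496	530.66	Aneuploid
Solanum lycopersicum	156	34075	950	Diploid
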