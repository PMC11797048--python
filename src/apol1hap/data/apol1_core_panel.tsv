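variant_id	chrom	pos	pos_alt_build	ref	alt	class	role
rs73885316	chr22	36265628	36661674	C	A	exonic	M1
rs73885319	chr22	36265860		A	G	exonic	G1_snp1
rs60910145	chr22	36265988		T	G	exonic	G1_snp2
rs71785313	chr22	36265995		AATAATT	A	exonic	G2_del
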