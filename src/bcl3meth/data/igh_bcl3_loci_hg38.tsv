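chrom	start	end	name	feature_class	strand
chr14	105583000	105588000	IGHA2	switch_region	-
chr14	105620000	105625000	IGHG4	switch_region	-
chr14	105639000	105645000	IGHG2	switch_region	-
chr14	105703500	105712000	IGHA1	switch_region	-
chr14	105736000	105744000	IGHG1	switch_region	-
chr14	105766000	105773000	IGHG3	switch_region	-
chr14	105851000	105857000	IGHM	switch_region	-
chr14	105863100	105863250	IGHJ6	J_gene	-
chr14	105880500	105880540	IGHD1_7	D_gene	-
chr19	44698528	44709657	CEACAM16	gene	-
chr19	44701400	44702900	CEACAM16_intron2	intron	-
chr19	44747705	44760044	BCL3	gene	+
chr19	44777865	44800040	CBLC	gene	+
chr19	44790000	44793500	CBLC_intron9	intron	+
chr19	44846175	44889228	NECTIN2	gene	-
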