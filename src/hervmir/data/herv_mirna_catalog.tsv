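chrom	start	end	mirna	family	subfamily
chr1	51059879	51059900	hsa-miR-4421	ERV1	MER52A
chr1	51060031	51060054	hsa-miR-6500-5p	ERV1	MER52A
chr1	51060072	51060092	hsa-miR-6500-3p	ERV1	MER52A
chr1	237471164	237471185	hsa-miR-4428	ERV1	LTR9A1
chr3	32506342	32506362	hsa-miR-548ay-5p	ERV1	LTR43
chr3	32506305	32506326	hsa-miR-548ay-3p	ERV1	LTR43
chr3	164171523	164171544	hsa-miR-1263	ERV1	MER39
chr3	176515103	176515120	hsa-miR-7977	ERV1	HUERS-P3-int
chr4	163093607	163093626	hsa-miR-4454	ERV1	HERV-H-int
chr6	155946809	155946829	hsa-miR-1202	ERV1	MER52A
chr7	64679069	64679090	hsa-miR-6839-5p	ERV1	LTR7C
chr8	1801133	1801154	hsa-miR-3674	ERV1	LTR8A
chr12	122695964	122695985	hsa-miR-9902	ERV1	HUERS-P1-int
chr15	85825655	85825673	hsa-miR-548ap-5p	ERV1	MER50
chr15	85825692	85825710	hsa-miR-548ap-3p	ERV1	MER50
chr17	82668281	82668301	hsa-miR-4525	ERV1	MER52D
chr18	39622153	39622172	hsa-miR-924	ERV1	MER101B
chr19	12920373	12920394	hsa-miR-5695	ERV1	MER39B
chr19	55123225	55123242	hsa-miR-7975	ERV1	HERV-H-int
chr3	183886860	183886879	hsa-miR-4448	ERVK	LTR13
chr2	12199138	12199159	hsa-miR-3681-5p	ERVL	LTR16D1
chr2	12199174	12199195	hsa-miR-3681-3p	ERVL	LTR16D1
chr4	66276890	66276911	hsa-miR-1269a	ERVL	MLT2B3
chr8	28505126	28505142	hsa-miR-4288	ERVL	LTR86B1
chr14	67441902	67441922	hsa-miR-5694	ERVL	MLT2B1
chr16	14907756	14907779	hsa-miR-3670	ERVL	LTR16A1
chr17	12917313	12917334	hsa-miR-1269b	ERVL	MLT2B3
chr20	60308534	60308552	hsa-miR-646	ERVL	LTR67B
chr22	30731569	30731590	hsa-miR-3200-5p	ERVL	LTR16D2
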