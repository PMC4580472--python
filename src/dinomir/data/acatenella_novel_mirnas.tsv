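name	sequence	length	precursor_length	gc_percent	dg
aca-miR43924-5p	GCGGAGGAAAAGAAACTAAC	20	96	52.50	-93.20
aca-miR4542336-3p	GTTCCGCTTTCTCGTCGC	18	96	52.50	-90.30
aca-miR35336-5p	CGGACTTGCCATTCCTAGCCT	21	187	42.10	-98.10
aca-miR311414-3p	AAAGGCTAGGAATTGCAATTC	21	187	42.10	-98.10
aca-miR129519-3p-1	CCATCAGCTGTTGCCATGTCGT	22	123	53.50	-73.90
aca-miR129519-3p-2	CCATCAGCTGTTGCCATGTCGT	22	175	52.80	-132.30
aca-miR312912-5p	AAAAGGCTGGGAATTGCAATTC	22	122	55.70	-73.20
aca-miR5257085-3p	GAAGGGCTGGAGATTGCAACT	21	122	55.70	-73.20
aca-miR456915-3p	CAAAATGGGCGGCAAGAAAGGCT	23	103	55.70	-67.80
aca-miR342562-5p	TTTTTTAAAAGGCTGGGAAT	20	56	38.70	-33.30
aca-miR126213-3p	CAACGAAAGGTTATCTTCCTGGAT	24	119	37.70	-59.30
aca-miR879241-3p	CGGAGGAAAAGAAACTAACA	20	96	42.40	-46
aca-miR254217-3p	CTCAGTCCTTGGGCTGGTTGCTCT	24	129	57.50	-101.20
aca-miR5619838-5p	GCCGCTGATAGAGGGCCTGCAACCT	25	146	65.10	-98.30
aca-miR190576-3p	CGAGCCATTCAAAGTCTGGACTTTG	25	95	46.90	-51.60
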