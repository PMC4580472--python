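miRNA	log2fc	p_chisq	call
osa-miR168a-5p	-2.06	0.0044	down
tae-miR159a	-2.05	0.0202	down
aca-miR43924-5p	-1.11	0.0000	down
zma-miR529-5p	-inf	0.0452	down
osa-miR2876-3p_R+1	+inf	0.0027	up
rgl-miR5139	1.12	0.0060	up
aca-miR456915-3p	1.21	0.0003	up
sbi-miR169c	1.23	0.0294	up
stu-miR169a-5p_R+1	1.23	0.0294	up
zma-miR169f-5p	1.23	0.0294	up
stu-miR171b-3p	1.38	0.0248	up
bdi-miR7732-3p_L-1_1ss11GC	1.79	0.0055	up
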