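mirna_name	log2fc_drought	p_class_drought	log2fc_rehydration	p_class_rehydration
gma-miR4995	2.59	***	2.92	***
ath-miR8175	2.36	***	1.89	***
gma-miR6300	2.10	***	1.98	***
ptc-miR6478	1.45	***	1.12	***
bdi-miR5054	1.03	**	1.68	***
gma-miR5368	2.02	***	1.06
osa-miR5072	1.38	*	0.69
bna-miR167d	1.37	*	0.34
hvu-miR172b-3p	1.07	*	0.26
hvu-miR156a/b	1.01	*	0.43
ppt-miR894	0.73	*	0.23
hvu-miR5051	-0.73	*	-2.06	***
ata-miR171a-3p	-0.93	*	-1.11	*
ata-miR168-3p	-0.96	***	-1.21	***
bdi-miR166e-3p	-1.81	***	-1.00	*
bdi-miR827-5p	-1.85	***	-1.01	*
hvu-miR171-5p	-2.20	***	-0.69	*
ata-miR166c-5p	-2.32	***	-1.96	***
ata-miR166a-5p	-2.45	***	-0.93	**
ata-miR1432-5p	-2.45	***	-2.06	***
ata-miR5168-5p	-4.20	***	-2.07	***
ata-miR396c-3p	-4.58	***	-1.66	***
aly-miR396b-5p	-0.63	*	-0.56
cme-miR166g	-0.65	*	0.06
ata-miR166c-3p	-0.73	*	0.01
ata-miR5168-3p	-0.82	**	-0.29
gma-miR156k	-0.86	**	-0.41
hvu-miR168-5p	-0.87	**	-0.29
csi-miR166d	-0.87	**	-0.24
aqc-miR166c	-0.87	*	-0.28
bdi-miR159a-3p	-0.90	*	0.09
hvu-miR159a/b	-1.12	***	-0.30
ata-miR398f-3p	-1.14	*	-0.49
ata-miR166d-5p	-1.17	**	-0.06
hvu-miR6196	-1.22	*	-0.54
osa-miR319a-3p.2-3p	-1.53	***	-0.23
ata-miR167c-3p	-1.58	**	0.10
ata-miR171c-5p	-1.60	**	0.50
aly-miR166a-5p	-1.60	***	-0.86
osa-miR166e-3p	-1.79	*	0.20
bdi-miR159b-5p.1	-1,93	***	-0.87
aly-miR399b-3p	-1.93	***	-0.58
hvu-miR172b-5p	-2.00	***	-0.40
ata-miR166e-5p	-2.03	*	-0.56
bdi-miR159b-5p.3	-2.24	**	0.25
bdi-miR164a-3p	-2.38	**	-0.47
hvu-miR5049f	-2.41	*	-0.53
ata-miR395a-3p	-2.54	***	0.48
ata-miR408-5p	-4.20	***	-0.93
aly-miR164a-5p	0.12		1.88	***
bdi-miR156h-3p	1.11		1.48	*
cme-miR156j	0.79		0.87	*
ahy-miR159	0.65		0.65	*
zma-miR168a-3p	0.03		-0.86	**
bdi-miR1432	-0.30		-0.95	**
tae-miR9773	-0.64		-1.04	**
ata-miR156c-3p	-1.25		-1.12	*
bdi-miR408-3p	-0.28		-1.51	*
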