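phas_id	putative_function	overlapping_gene	trigger	mirna_length
PHAS21-4	CSC1-like protein	maker-Fvb1-2-snap-gene-74.69	miR11301a/b/c; miR11285a/b	21;22
PHAS21-8	CSC1-like protein	maker-Fvb1-3-snap-gene-60.54	miR11301a/b/c; miR11285a/b	21;22
PHAS21-9	PPR	Intergenic	miR11285a/b	22
PHAS21-10	ncRNA	Intergenic	miR482a/b/y	22/22/21
PHAS21-13	NULL	maker-Fvb2-1-augustus-gene-234.53 (E3 ubiquitin-protein ligase RNF126-like)	miR482n/s/x; miR2118b	22
PHAS21-17	ncRNA	maker-Fvb3-1-augustus-gene-207.32	miRN14	21
PHAS21-18	ncRNA	maker-Fvb3-1-augustus-gene-207.33	miRN14	21
PHAS21-23	PPR	augustus_masked-Fvb3-2-processed-gene-267.11 (PPR); augustus_masked-Fvb3-2-processed-gene-267.12 (PPR)	miR11301a/b/c; miR11285a/b; miR171d/e/f	21; 22
PHAS21-25	uncharacterized mRNA	Intergenic	miR482a/b	22
PHAS21-26	ncRNA	Intergenic	miRN14	21
PHAS21-27	ncRNA	Intergenic	miRN14	21
PHAS21-28	PPR	snap_masked-Fvb3-4-processed-gene-39.28 (PPR); maker-Fvb3-4-snap-gene-39.55 (PPR)	miR11301a/b/c	21
PHAS21-29	ASA1	augustus_masked-Fvb3-4-processed-gene-44.0 (ASA1)	miR156n	20
PHAS21-30	ncRNA	maker-Fvb3-4-augustus-gene-194.36	miRN14	21
PHAS21-33	HLCS	maker-Fvb4-1-snap-gene-75.30	miR390a/b/c/d/e/f/g/h/i	21
PHAS21-34	NULL	Intergenic	miRN11a/b/c	22
PHAS21-36	ncRNA	Intergenic	miR11301a/b/c; miR164c	21; 20
PHAS21-39	NULL	Intergenic	miR11286a; miRN11a/b/c	21; 22
PHAS21-41	TAS3-like	maker-Fvb4-3-augustus-gene-122.25	miR390a/b/c/d/e/f/g/h/i	21
PHAS21-42	NULL	snap_masked-Fvb4-3-processed-gene-219.12	miR390a/b/c/d/e/f/g/h/i	21
PHAS21-43	NULL	Intergenic	miR390a/b/c/d/e/f/g/h/i	21
PHAS21-44	NULL	Intergenic	miR11285a/b	22
PHAS21-47	TAS3-like	maker-Fvb4-4-augustus-gene-90.46	miR390a/b/c/d/e/f/g/h/i	21
PHAS21-48	NULL	maker-Fvb4-4-snap-gene-187.25 (E3 ubiquitin-protein ligase XBAT32)	miR390a/b/c/d/e/f/g/h/i	21
PHAS21-50	MIR159c	Intergenic	miR319a/b/c/d/e/f/g/h; miR159a/b/c/d/e/f/g/h/i/j/k/l	20; 21
PHAS21-54	MIR159c	Intergenic	miR319a/b/c/d/e/f/g/h; miR159a/b/c/d/e/f/g/h/i/j/k/l	20; 21
PHAS21-56	MIR159c	Intergenic	miR319a/b/c/d/e/f/g/h; miR159a/b/c/d/e/f/g/h/i/j/k/l	20; 21
PHAS21-57	NULL	maker-Fvb6-1-augustus-gene-4.51	miR482p/t	21
PHAS21-60	ncRNA	augustus_masked-Fvb6-1-processed-gene-36.17 (CM3)	miR482p/t	21
PHAS21-62	NULL	Intergenic	miR390a/b/c/d/e/f/g/h/i; miR482c/f/h/u/v/w	21
PHAS21-63	NULL	Intergenic	miR395a/b/c/d/e/f/g/h/i/j/k/l/m/n/o/p; miRN3	21
PHAS21-65	ncRNA	snap_masked-Fvb6-1-processed-gene-319.21	miR482n/s/x; miR2118b	22
PHAS21-66	ncRNA	Intergenic	miRN11a/b/c; miR482d/e/g	22; 21
PHAS21-67	NULL	Intergenic	miR395a/b/c/d/e/f/g/h/i/j/k/l/m/n/o/p; miRN3	21
PHAS21-68	NULL	maker-Fvb6-2-snap-gene-237.55	miR482c/d/e/f/g/h/u/v/w/x; miR2118b	21; 22
PHAS21-69	NULL	augustus_masked-Fvb6-2-processed-gene-304.5 (CM3)	miR482p/t	21
PHAS21-73	NULL	maker-Fvb6-3-augustus-gene-30.84	miR482p/t	21
PHAS21-74	NULL	Intergenic	miR482c/f/h/u/v/w; miR390a/b/c/d/e/f/g/h/i	21
PHAS21-76	uncharacterized mRNA	maker-Fvb6-3-snap-gene-381.45	miR11287a/b; miR482n/s/x; miR2118b; miRN14; miR7125a/b	21; 22
PHAS21-81	40S ribosomal protein S29	snap_masked-Fvb7-4-processed-gene-5.26	miRN11a/b/c	22
PHAS24-2	ncRNA	Intergenic	miRN29	21
PHAS24-11	CSC1-like protein	Intergenic	miR11285a/b	22
PHAS24-14	NULL	Intergenic	miR482d/e/g	21
PHAS24-19	uncharacterized mRNA	Intergenic	miR172a	20
PHAS24-26	uncharacterized mRNA	Intergenic	miR172a	20
PHAS24-29	ncRNA	Intergenic	miRN14	21
PHAS24-30	ncRNA	Intergenic	miRN14	21
PHAS24-42	uncharacterized mRNA	Intergenic	miR11288b/e/i/l/n; miR395a/b/c/d/e/f/g/h/i/j/k/l/m/n/o/p	21
PHAS24-44	uncharacterized mRNA	Intergenic	miR6275a/b/c/d	21
PHAS24-47	ncRNA	maker-Fvb4-3-snap-gene-7.49 (RNA helicase)	miR156r/w; miRN16	20; 22
PHAS24-71	uncharacterized mRNA	Intergenic	miR172a	20
PHAS24-74	ncRNA	Intergenic	miRN29	21
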