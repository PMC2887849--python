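locus	group	repeat_motif	allele_count	H_o	H_e	percent_missing
euphy2	1	CAG	20	0.42	0.72	0.60
euphy3	1	ATC	18	0.52	0.83	0.84
euphy21	1	CAA	9	0.18	0.24	1.32
euphy69	1	GTT	13	0.17	0.39	3.59
euphy14	2	TACA	32	0.15	0.68	14.0
euphy61	2	AC	42	0.44	0.87	12.9
euphy35	3	TG	56	0.33	0.96	13.1
euphy50	3	CA,A	28	0.22	0.85	22.5
euphy37	4	C,CA	21	0.41	0.80	2.28
euphy47	4	AT	34	0.44	0.87	5.99
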