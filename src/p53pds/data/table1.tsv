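cancer_type	n_samples	n_mutant	n_wildtype	pct_mutant
OV	206	192	14	93.2
UCS	57	52	5	91.2
ESCA	184	158	26	85.9
LUSC	482	403	79	83.6
READ	146	107	39	73.3
HNSC	501	353	148	70.5
PAAD	169	104	65	61.5
COAD	405	223	182	55.1
LUAD	512	260	252	50.8
LGG	524	257	267	49.0
STAD	411	201	210	48.9
BLCA	406	198	208	48.8
UCEC	529	203	326	38.4
SARC	237	86	151	36.3
GBM	158	55	103	34.8
BRCA	1023	349	674	34.1
KICH	66	21	45	31.8
LIHC	360	108	252	30.0
SKCM	467	72	395	15.4
PRAD	494	59	435	11.9
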