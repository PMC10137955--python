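sample_id	pos	ref	ref_freq	alt	alt_freq	genotype
Family1-M	152	T	29.76	C	70.24	152Y
Family1-C	152	T	31.07	C	68.93	152Y
P01-H	251	G	50.91	A	49.09	251R
P14-H	1227	G	75.31	A	24.69	1227R
P15-H	1606	G	81.84	A	18.16	1606R
P09-H	3290	T	84.79	C	15.21	3290Y
Family8-M	3386	T	64.05	C	35.95	3386Y
Family8-C	3386	T	74.24	C	25.76	3386Y
P09-H	4776	G	85.36	C	14.64	4776S
P18-H	5591	G	85.00	A	15.00	5591R
P08-H	5843	A	89.16	G	10.84	5843R
P08-B	9083	T	92.69	C	7.30	9083Y
P15-B	9083	T	80.16	C	19.84	9083Y
P01-H	11118	T	93.03	C	6.97	11118Y
Family3-M	12361	A	32.08	G	67.92	12361R
P08-H	13269	A	90.48	G	9.52	13269R
P12-B	13678	C	89.29	A	10.71	13678M
P08-H	13679	C	90.66	A	9.34	13679M
P13-H	13679	C	92.13	A	7.87	13679M
P03-B	13683	C	93.61	A	6.39	13683M
P14-B	13683	C	89.75	G	10.25	13683S
P12-B	14215	T	85.91	C	14.09	14215Y
P18-H	14215	T	86.42	C	13.58	14215Y
Family7-M	15115	T	91.28	C	8.72	15115Y
P15-B	16154	T	88.41	C	11.59	16154Y
P18-B	16278	C	92.94	T	7.06	16278Y
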