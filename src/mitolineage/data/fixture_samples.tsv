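sample_id	individual_id	tissue
P01-B	P01	blood
P01-H	P01	hair
P03-B	P03	blood
P03-H	P03	hair
P04-B	P04	blood
P04-H	P04	hair
P06-B	P06	blood
P06-H	P06	hair
P08-B	P08	blood
P08-H	P08	hair
P09-B	P09	blood
P09-H	P09	hair
P12-B	P12	blood
P12-H	P12	hair
P13-B	P13	blood
P13-H	P13	hair
P14-B	P14	blood
P14-H	P14	hair
P15-B	P15	blood
P15-H	P15	hair
P18-B	P18	blood
P18-H	P18	hair
JX-N	JX-N	blood
JX-M1	JX-M1	blood
JX-M2	JX-M2	blood
JX-C1	JX-C1	blood
JX-C2	JX-C2	blood
JX-C3	JX-C3	blood
Family1-M	Family1-M	blood
Family1-C	Family1-C	blood
Family2-M	Family2-M	blood
Family2-C	Family2-C	blood
Family3-M	Family3-M	blood
Family3-C	Family3-C	blood
Family4-M	Family4-M	blood
Family4-C	Family4-C	blood
Family5-M	Family5-M	blood
Family5-C	Family5-C	blood
Family6-M	Family6-M	blood
Family6-C	Family6-C	blood
Family7-M	Family7-M	blood
Family7-C	Family7-C	blood
Family8-M	Family8-M	blood
Family8-C	Family8-C	blood
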