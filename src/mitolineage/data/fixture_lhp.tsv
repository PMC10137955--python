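sample_id	region	calls
P01-B	302-315	309.1C 315.1C
P01-H	302-315	315.1C
P03-B	302-315	309.1C 315.1C
P03-H	302-315	309.1c 315.1C
P04-B	302-315	309.1C 315.1C
P04-H	302-315	309.1C 315.1C
P06-B	302-315	309.1C 315.1C
P06-H	302-315	309.1C 315.1C
P08-B	302-315	309.1C 315.1C
P08-H	302-315	309.1C 315.1C
P09-B	302-315	309.1c 315.1C
P09-H	302-315	309.1c 315.1C
P12-B	302-315	309.1C 315.1C
P12-H	302-315	309.1C 315.1C
P13-B	302-315	309.1C 315.1C
P13-H	302-315	309.1c 315.1C
P14-B	302-315	309.1C 315.1C
P14-H	302-315	309.1c 315.1C
P15-B	302-315	309.1C 315.1C
P15-H	302-315	309.1C 315.1C
P18-B	302-315	309.1C 315.1C
P18-H	302-315	309.1C 315.1C
JX-N	302-315	309.1c 315.1C
JX-M1	302-315	309.1c 315.1C
JX-M2	302-315	309.1C 315.1C
JX-C1	302-315	309.1c 315.1C
JX-C2	302-315	309.1c 315.1C
JX-C3	302-315	309.1c 315.1C
Family1-M	302-315	309.1C 315.1C
Family1-C	302-315	309.1C 315.1C
Family2-M	302-315	315.1C
Family2-C	302-315	315.1C
Family3-M	302-315	309.1c 315.1C
Family3-C	302-315	309.1C 315.1C
Family4-M	302-315	309.1C 315.1C
Family4-C	302-315	309.1C 315.1C
Family5-M	302-315	309.1c 315.1C
Family5-C	302-315	309.1c 315.1C
Family6-M	302-315	309.1C 309.2c 315.1C
Family6-C	302-315	309.1C 309.2c 315.1C
Family7-M	302-315	309.1C 315.1C
Family7-C	302-315	309.1C 315.1C
Family8-M	302-315	309.1C 315.1C
Family8-C	302-315	309.1C 315.1C
P01-B	955-966	961c 965.1c 965.2c
P01-H	955-966	961C 965.1C 965.2c
P03-B	955-966	961C 965.1c 965.2c 965.3c
P03-H	955-966	961c 965.1c 965.2c 965.3c
P04-B	955-966	961c 965.1c 965.2c
P04-H	955-966	961C 965.1C 965.2c
P06-B	955-966	961C 965.1c 965.2c 965.3c
P06-H	955-966	961C 965.1C 965.2c
P08-B	955-966	961C 965.1c 965.2c
P08-H	955-966	961C 965.1c 965.2c
P09-B	955-966	961C 965.1c 965.2c
P09-H	955-966	961C 965.1c 965.2c
P12-B	955-966	961C 965.1c 965.2c
P12-H	955-966	961C 965.1c 965.2c
P13-B	955-966	961C 965.1C 965.2c
P13-H	955-966	961C 965.1C 965.2c
P14-B	955-966	961C 965.1c 965.2c 965.3c
P14-H	955-966	961C 965.1C 965.2c
P15-B	955-966	961C 965.1c 965.2c
P15-H	955-966	961C
P18-B	955-966	961C 965.1c 965.2c
P18-H	955-966	961C 965.1c 965.2c
Family4-M	955-966	961c 965.1c 965.2c
Family4-C	955-966	961C 965.1c 965.2c
Family7-M	16180-16194	16183C 16189C 16193.1c
Family7-C	16180-16194	16183C 16189C 16193.1c
Family8-M	16180-16194	16182C 16183C 16189C 16193.1c
Family8-C	16180-16194	16182C 16183C 16189C 16193.1c
Family2-M	249	249DEL
Family2-C	249	249DEL
Family6-M	249	249DEL
Family6-C	249	249DEL
Family5-M	8272-8280	8272DEL 8273DEL 8274DEL 8275c 8276c 8277t 8278c 8279t 8280a
Family5-C	8272-8280	8272DEL 8273DEL 8274DEL 8275c 8276c 8277t 8278c 8279t 8280a
P01-B	514-524	523a 524c
P01-H	514-524	523a 524c
P03-B	514-524	523a 524c
P03-H	514-524	523a 524c
P04-B	514-524	523a 524c
P04-H	514-524	523a 524c
P06-B	514-524	523a 524c
P06-H	514-524	523a 524c
P08-B	514-524	523a 524c
P08-H	514-524	523a 524c
P09-B	514-524	523a 524c
P09-H	514-524	523a 524c
P12-B	514-524	523a 524c
P12-H	514-524	523a 524c
P13-B	514-524	523a 524c
P13-H	514-524	523a 524c
P14-B	514-524	523a 524c
P14-H	514-524	523a 524c
P15-B	514-524	523a 524c
P15-H	514-524	523a 524c
P18-B	514-524	523a 524c
P18-H	514-524	523a 524c
JX-N	514-524	523a 524c
JX-M1	514-524	523a 524c
JX-M2	514-524	523a 524c
JX-C1	514-524	523a 524c
JX-C2	514-524	523a 524c
JX-C3	514-524	523a 524c
Family1-M	514-524	523a 524c
Family1-C	514-524	523a 524c
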