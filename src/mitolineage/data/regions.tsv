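name	start	end
CR	16024	576
TF	577	647
RNR1	648	1601
TV	1602	1670
RNR2	1671	3229
TL1	3230	3304
ND1	3307	4262
TI	4263	4331
TQ	4329	4400
TM	4402	4469
ND2	4470	5511
TW	5512	5579
TA	5587	5655
TN	5657	5729
TC	5761	5826
TY	5826	5891
CO1	5904	7445
TS1	7446	7514
TD	7518	7585
CO2	7586	8269
TK	8295	8364
ATP8	8366	8572
ATP6	8527	9207
CO3	9207	9990
TG	9991	10058
ND3	10059	10404
TR	10405	10469
ND4L	10470	10766
ND4	10760	12137
TH	12138	12206
TS2	12207	12265
TL2	12266	12336
ND5	12337	14148
ND6	14149	14673
TE	14674	14742
CYB	14747	15887
TT	15888	15953
TP	15956	16023
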