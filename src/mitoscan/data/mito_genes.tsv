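gene	start	end	strand	coding
TRNF	577	647	+	0
RNR1	648	1601	+	0
TRNV	1602	1670	+	0
RNR2	1671	3229	+	0
TRNL1	3230	3304	+	0
ND1	3307	4262	+	1
TRNI	4263	4331	+	0
TRNQ	4329	4400	-	0
TRNM	4402	4469	+	0
ND2	4470	5511	+	1
TRNW	5512	5579	+	0
TRNA	5587	5655	-	0
TRNN	5657	5729	-	0
TRNC	5761	5826	-	0
TRNY	5826	5891	-	0
COX1	5904	7445	+	1
TRNS1	7446	7514	-	0
TRND	7518	7585	+	0
COX2	7586	8269	+	1
TRNK	8295	8364	+	0
ATP8	8366	8572	+	1
ATP6	8527	9207	+	1
COX3	9207	9990	+	1
TRNG	9991	10058	+	0
ND3	10059	10404	+	1
TRNR	10405	10469	+	0
ND4L	10470	10766	+	1
ND4	10760	12137	+	1
TRNH	12138	12206	+	0
TRNS2	12207	12265	+	0
TRNL2	12266	12336	+	0
ND5	12337	14148	+	1
ND6	14149	14673	-	1
TRNE	14674	14742	-	0
CYTB	14747	15887	+	1
TRNT	15888	15953	+	0
TRNP	15956	16023	-	0
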