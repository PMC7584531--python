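#locus	start	end	strand	product_class
MT-CR	16024	16569	heavy	noncoding
MT-CR	1	576	heavy	noncoding
MT-TF	577	647	heavy	tRNA
MT-RNR1	648	1601	heavy	rRNA
MT-TV	1602	1670	heavy	tRNA
MT-RNR2	1671	3229	heavy	rRNA
MT-TL1	3230	3304	heavy	tRNA
MT-ND1	3307	4262	heavy	complexI
MT-TI	4263	4331	heavy	tRNA
MT-TQ	4332	4400	light	tRNA
MT-TM	4402	4469	heavy	tRNA
MT-ND2	4470	5511	heavy	complexI
MT-TW	5512	5579	heavy	tRNA
MT-TA	5587	5655	light	tRNA
MT-TN	5657	5729	light	tRNA
MT-TC	5761	5826	light	tRNA
MT-TY	5827	5891	light	tRNA
MT-CO1	5904	7445	heavy	complexIV
MT-TS1	7446	7514	light	tRNA
MT-TD	7518	7585	heavy	tRNA
MT-CO2	7586	8269	heavy	complexIV
MT-TK	8295	8364	heavy	tRNA
MT-ATP8	8366	8572	heavy	ATPsynthase
MT-ATP6	8527	9206	heavy	ATPsynthase
MT-CO3	9207	9990	heavy	complexIV
MT-TG	9991	10058	heavy	tRNA
MT-ND3	10059	10404	heavy	complexI
MT-TR	10405	10469	heavy	tRNA
MT-ND4L	10470	10766	heavy	complexI
MT-ND4	10760	12137	heavy	complexI
MT-TH	12138	12206	heavy	tRNA
MT-TS2	12207	12265	heavy	tRNA
MT-TL2	12266	12336	heavy	tRNA
MT-ND5	12337	14148	heavy	complexI
MT-ND6	14149	14673	light	complexI
MT-TE	14674	14742	light	tRNA
MT-CYB	14747	15887	heavy	complexIII
MT-TT	15888	15953	heavy	tRNA
MT-TP	15956	16023	light	tRNA
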