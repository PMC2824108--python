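chromosome	total_chr_length	nonredundant_clone_length	clone_length_total	passed_aligned_sequence
1	197195432	189902383	1385443533	13593208
2	181748087	177813774	1348761746	13129801
3	159599783	155666906	1151145108	11396911
4	155630120	150659365	1134909770	10944727
5	152537259	146223145	1009782448	9773915
6	149517037	145684306	1049822257	10281087
7	152524553	140866414	1007473869	9637732
8	131738871	123985369	907535329	8826036
9	124076172	120302728	916247038	8800500
10	129993255	125971520	897618520	8764981
11	121843856	118333935	924494065	8842955
12	121257530	117098461	854759223	8258226
13	120284312	116142787	888982416	8609816
14	125194864	119290632	846844974	8247811
15	103494974	100431693	735484668	7116922
16	98319150	94516190	692930172	6811564
17	95272651	91304604	690760336	6680800
18	90772031	86713096	655698203	6460483
19	61342430	57670646	421571236	4064957
X	166650296	160833108	1095695031	10991837
Y	15902555	0	0	0
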