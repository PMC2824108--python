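chromosome	total_chr_length	nonredundant_clone_length	clone_length_total	passed_aligned_sequence
1	197195432	188433001	1046993130	7724484
2	181748087	175429538	942386790	6916061
3	159599783	154711914	875284125	6490661
4	155630120	148498769	827737353	6127905
5	152537259	144530268	733517218	5404820
6	149517037	143599805	775532299	5768104
7	152524553	135008655	644735047	4788996
8	131738871	121214563	606581664	4522109
9	124076172	118654230	598157862	4362992
10	129993255	124749578	675601360	4987613
11	121843856	115930403	605273345	4474962
12	121257530	115274597	604649354	4482487
13	120284312	114926992	609116213	4517988
14	125194864	116442268	607970623	4531884
15	103494974	99239967	543851152	3998763
16	98319150	92840807	534474134	3928889
17	95272651	89677039	468395835	3456144
18	90772031	85715767	456115712	3373974
19	61342430	56286798	291811698	2148157
X	166650296	148955095	469399660	3543869
Y	15902555	2427223	9762866	80060
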