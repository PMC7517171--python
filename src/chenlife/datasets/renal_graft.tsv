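0.0350	0.0680	0.1000	0.1010	0.1670	0.1680	0.1970	0.2130	0.2330	0.2340
0.5080	0.5080	0.5330	0.6330	0.7670	0.7680	0.7700	1.0660	1.2670	1.3000
1.6000	1.6390	1.8030	1.8670	2.1800	2.6670	2.9670	3.3280	3.3930	3.7000
3.8030	4.3110	4.8670	5.1800	6.2330	6.3670	6.6000	6.6000	7.1800	7.6670
7.7330	7.8000	7.9330	7.9670	8.0160	8.3000	8.4100	8.6070	8.6670	8.8000
9.1000	9.2330	10.541	10.607	10.633	10.667	10.869	11.067	11.180	11.443
12.213	12.508	12.533	13.467	13.800	14.267	14.475	14.500	15.213	15.333
15.525	15.533	15.541	15.934	16.200	16.300	16.344	16.600	16.700	16.933
17.033	17.067	17.475	17.667	17.700	17.967	18.115	18.115	18.933	18.934
19.508	19.574	19.733	20.148	20.180	20.900	21.167	21.233	21.600	22.100
22.148	22.180	22.180	22.267	22.300	22.500	22.533	22.867	23.738	24.082
24.180	24.705	25.213	25.705	29.705	30.443	31.667	31.934	32.180	32.367
32.672	32.705	33.148	33.567	33.770	33.869	34.836	34.869	34.934	35.738
36.180	36.213	39.410	39.433	39.672	40.001	41.733	41.734	42.311	42.869
43.180	43.279	43.902	44.267	44.475	44.900	45.148	46.451
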