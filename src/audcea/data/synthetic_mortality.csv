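# SYNTHETIC all-cause annual death probability by age and sex
# (Gompertz-shaped stand-in for a national life table; not register data)
age,sex,annual_death_probability
18,male,0.000148797
18,female,9.67183e-05
19,male,0.00016343
19,female,0.00010623
20,male,0.000179502
20,female,0.000116676
21,male,0.000197154
21,female,0.00012815
22,male,0.000216542
22,female,0.000140753
23,male,0.000237837
23,female,0.000154594
24,male,0.000261226
24,female,0.000169797
25,male,0.000286915
25,female,0.000186495
26,male,0.00031513
26,female,0.000204835
27,male,0.00034612
27,female,0.000224978
28,male,0.000380158
28,female,0.000247102
29,male,0.000417542
29,female,0.000271403
30,male,0.000458604
30,female,0.000298092
31,male,0.000503703
31,female,0.000327407
32,male,0.000553237
32,female,0.000359604
33,male,0.000607642
33,female,0.000394967
34,male,0.000667398
34,female,0.000433808
35,male,0.00073303
35,female,0.000476469
36,male,0.000805116
36,female,0.000523325
37,male,0.000884291
37,female,0.000574789
38,male,0.000971252
38,female,0.000631314
39,male,0.00106677
39,female,0.000693397
40,male,0.00117167
40,female,0.000761586
41,male,0.00128689
41,female,0.00083648
42,male,0.00141345
42,female,0.00091874
43,male,0.00155244
43,female,0.00100909
44,male,0.00170511
44,female,0.00110832
45,male,0.00187279
45,female,0.00121732
46,male,0.00205696
46,female,0.00133703
47,male,0.00225925
47,female,0.00146851
48,male,0.00248142
48,female,0.00161292
49,male,0.00272544
49,female,0.00177154
50,male,0.00299346
50,female,0.00194575
51,male,0.00328784
51,female,0.0021371
52,male,0.00361117
52,female,0.00234726
53,male,0.00396629
53,female,0.00257809
54,male,0.00435633
54,female,0.00283162
55,male,0.00478474
55,female,0.00311008
56,male,0.00525527
56,female,0.00341592
57,male,0.00577207
57,female,0.00375185
58,male,0.0063397
58,female,0.0041208
59,male,0.00696314
59,female,0.00452604
60,male,0.0076479
60,female,0.00497113
61,male,0.00839999
61,female,0.00545999
62,male,0.00922605
62,female,0.00599693
63,male,0.0101333
63,female,0.00658667
64,male,0.0111299
64,female,0.0072344
65,male,0.0122244
65,female,0.00794583
66,male,0.0134265
66,female,0.00872723
67,male,0.0147469
67,female,0.00958546
68,male,0.0161971
68,female,0.0105281
69,male,0.0177899
69,female,0.0115634
70,male,0.0195394
70,female,0.0127006
71,male,0.0214609
71,female,0.0139496
72,male,0.0235713
72,female,0.0153214
73,male,0.0258893
73,female,0.0168281
74,male,0.0284353
74,female,0.0184829
75,male,0.0312316
75,female,0.0203005
76,male,0.0343029
76,female,0.0222969
77,male,0.0376763
77,female,0.0244896
78,male,0.0413814
78,female,0.0268979
79,male,0.0454508
79,female,0.029543
80,male,0.0499204
80,female,0.0324483
81,male,0.0548296
81,female,0.0356393
82,male,0.0602216
82,female,0.039144
83,male,0.0661438
83,female,0.0429935
84,male,0.0726484
84,female,0.0472214
85,male,0.0797926
85,female,0.0518652
86,male,0.0876394
86,female,0.0569656
87,male,0.0962579
87,female,0.0625676
88,male,0.105724
88,female,0.0687205
89,male,0.116121
89,female,0.0754785
90,male,0.12754
90,female,0.0829011
91,male,0.140082
91,female,0.0910536
92,male,0.153858
92,female,0.100008
93,male,0.168989
93,female,0.109843
94,male,0.185607
94,female,0.120644
95,male,0.203859
95,female,0.132509
96,male,0.223907
96,female,0.14554
97,male,0.245926
97,female,0.159852
98,male,0.27011
98,female,0.175572
99,male,0.296673
99,female,0.192837
100,male,0.325848
100,female,0.211801
101,male,0.357892
101,female,0.23263
102,male,0.393087
102,female,0.255506
103,male,0.431743
103,female,0.280633
104,male,0.474201
104,female,0.30823
105,male,0.520834
105,female,0.338542
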