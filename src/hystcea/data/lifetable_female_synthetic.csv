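age,annual_death_prob
18,0.000384
19,0.000398
20,0.000414
21,0.000431
22,0.000450
23,0.000471
24,0.000494
25,0.000520
26,0.000547
27,0.000578
28,0.000612
29,0.000649
30,0.000689
31,0.000734
32,0.000784
33,0.000838
34,0.000897
35,0.000963
36,0.001035
37,0.001114
38,0.001201
39,0.001297
40,0.001402
41,0.001518
42,0.001645
43,0.001785
44,0.001940
45,0.002109
46,0.002295
47,0.002500
48,0.002725
49,0.002973
50,0.003245
51,0.003545
52,0.003874
53,0.004236
54,0.004634
55,0.005072
56,0.005554
57,0.006084
58,0.006666
59,0.007306
60,0.008011
61,0.008785
62,0.009637
63,0.010573
64,0.011603
65,0.012735
66,0.013980
67,0.015350
68,0.016856
69,0.018511
70,0.020332
71,0.022335
72,0.024537
73,0.026958
74,0.029621
75,0.032549
76,0.035769
77,0.039309
78,0.043203
79,0.047485
80,0.052193
81,0.057371
82,0.063064
83,0.069325
84,0.076210
85,0.083781
86,0.092107
87,0.101262
88,0.111330
89,0.122401
90,0.134576
91,0.147963
92,0.162685
93,0.178874
94,0.196677
95,0.216254
96,0.237781
97,0.261454
98,0.287487
99,0.316113
100,1.000000
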