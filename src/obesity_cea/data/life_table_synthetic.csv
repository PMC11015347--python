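age,sex,qx
20,female,0.00072385
21,female,0.00075259
22,female,0.00078387
23,female,0.00081793
24,female,0.000855
25,female,0.00089536
26,female,0.00093931
27,female,0.00098715
28,female,0.00103923
29,female,0.00109592
30,female,0.00115765
31,female,0.00122484
32,female,0.001298
33,female,0.00137763
34,female,0.00146433
35,female,0.0015587
36,female,0.00166144
37,female,0.00177328
38,female,0.00189503
39,female,0.00202757
40,female,0.00217184
41,female,0.00232888
42,female,0.00249984
43,female,0.00268592
44,female,0.00288848
45,female,0.00310895
46,female,0.00334894
47,female,0.00361014
48,female,0.00389445
49,female,0.00420388
50,female,0.00454066
51,female,0.00490718
52,female,0.00530607
53,female,0.00574017
54,female,0.00621256
55,female,0.0067266
56,female,0.00728595
57,female,0.00789456
58,female,0.00855674
59,female,0.00927717
60,female,0.01006092
61,female,0.01091349
62,female,0.01184087
63,female,0.01284953
64,female,0.0139465
65,female,0.01513941
66,female,0.01643651
67,female,0.01784675
68,female,0.01937979
69,female,0.02104613
70,female,0.02285707
71,female,0.02482487
72,female,0.02696275
73,female,0.02928495
74,female,0.03180688
75,female,0.0345451
76,female,0.03751743
77,female,0.04074306
78,female,0.04424257
79,female,0.04803803
80,female,0.05215308
81,female,0.05661298
82,female,0.06144469
83,female,0.06667693
84,female,0.07234019
85,female,0.07846682
86,female,0.08509099
87,female,0.0922487
88,female,0.09997777
89,female,0.10831774
90,female,0.11730975
91,female,0.12699644
92,female,0.13742168
93,female,0.14863031
94,female,0.16066779
95,female,0.17357977
96,female,0.18741152
97,female,0.2022073
98,female,0.21800956
99,female,0.23485807
100,female,0.25278885
101,female,0.27183295
102,female,0.29201513
103,female,0.31335232
104,female,0.33585198
105,female,0.35951029
106,female,0.38431029
107,female,0.41021991
108,female,0.43718998
109,female,0.46515238
110,female,0.49401826
20,male,0.00117293
21,male,0.00122376
22,male,0.00127909
23,male,0.00133933
24,male,0.00140492
25,male,0.00147631
26,male,0.00155403
27,male,0.00163864
28,male,0.00173075
29,male,0.00183102
30,male,0.00194018
31,male,0.002059
32,male,0.00218836
33,male,0.00232916
34,male,0.00248244
35,male,0.00264929
36,male,0.00283091
37,male,0.00302861
38,male,0.0032438
39,male,0.00347802
40,male,0.00373297
41,male,0.00401046
42,male,0.00431248
43,male,0.00464119
44,male,0.00499893
45,male,0.00538827
46,male,0.00581198
47,male,0.00627307
48,male,0.00677483
49,male,0.00732081
50,male,0.00791489
51,male,0.00856127
52,male,0.00926452
53,male,0.01002959
54,male,0.01086186
55,male,0.01176717
56,male,0.01275186
57,male,0.01382279
58,male,0.01498741
59,male,0.01625379
60,male,0.01763067
61,male,0.01912751
62,male,0.02075455
63,male,0.02252286
64,male,0.02444443
65,male,0.02653218
66,male,0.02880006
67,male,0.03126314
68,male,0.03393764
69,male,0.03684101
70,male,0.03999205
71,male,0.04341091
72,male,0.04711924
73,male,0.05114022
74,male,0.05549864
75,male,0.06022097
76,male,0.0653354
77,male,0.07087194
78,male,0.07686237
79,male,0.08334035
80,male,0.09034137
81,male,0.09790271
82,male,0.10606342
83,male,0.11486421
84,male,0.1243473
85,male,0.13455621
86,male,0.14553555
87,male,0.15733063
88,male,0.16998708
89,male,0.18355034
90,male,0.198065
91,male,0.21357413
92,male,0.23011834
93,male,0.24773482
94,male,0.26645616
95,male,0.28630906
96,male,0.30731281
97,male,0.32947774
98,male,0.35280343
99,male,0.37727685
100,male,0.40287042
101,male,0.42954005
102,male,0.45722318
103,male,0.48583704
104,male,0.51527701
105,male,0.54541547
106,male,0.57610105
107,male,0.60715858
108,male,0.63838992
109,male,0.66957565
110,male,0.70047806
20,combined,0.00094842
21,combined,0.0009882
22,combined,0.00103151
23,combined,0.00107866
24,combined,0.00113
25,combined,0.00118588
26,combined,0.00124672
27,combined,0.00131295
28,combined,0.00138505
29,combined,0.00146354
30,combined,0.00154899
31,combined,0.00164201
32,combined,0.00174328
33,combined,0.00185351
34,combined,0.00197351
35,combined,0.00210415
36,combined,0.00224635
37,combined,0.00240114
38,combined,0.00256964
39,combined,0.00275306
40,combined,0.00295271
41,combined,0.00317003
42,combined,0.00340657
43,combined,0.00366403
44,combined,0.00394426
45,combined,0.00424927
46,combined,0.00458122
47,combined,0.0049425
48,combined,0.00533568
49,combined,0.00576357
50,combined,0.00622921
51,combined,0.00673591
52,combined,0.00728727
53,combined,0.0078872
54,combined,0.00853993
55,combined,0.00925009
56,combined,0.01002268
57,combined,0.01086312
58,combined,0.01177731
59,combined,0.01277164
60,combined,0.01385306
61,combined,0.01502906
62,combined,0.0163078
63,combined,0.0176981
64,combined,0.01920951
65,combined,0.02085237
66,combined,0.02263784
67,combined,0.02457801
68,combined,0.02668593
69,combined,0.02897569
70,combined,0.03146245
71,combined,0.0341626
72,combined,0.03709373
73,combined,0.0402748
74,combined,0.04372613
75,combined,0.04746954
76,combined,0.0515284
77,combined,0.05592768
78,combined,0.06069406
79,combined,0.06585594
80,combined,0.07144352
81,combined,0.07748882
82,combined,0.0840257
83,combined,0.09108986
84,combined,0.09871879
85,combined,0.10695176
86,combined,0.11582964
87,combined,0.12539482
88,combined,0.13569099
89,combined,0.14676282
90,combined,0.15865572
91,combined,0.17141531
92,combined,0.18508698
93,combined,0.19971519
94,combined,0.21534277
95,combined,0.23201001
96,combined,0.24975362
97,combined,0.2686056
98,combined,0.28859187
99,combined,0.30973078
100,combined,0.33203153
101,combined,0.35549233
102,combined,0.38009858
103,combined,0.4058209
104,combined,0.43261317
105,combined,0.46041061
106,combined,0.48912798
107,combined,0.51865808
108,combined,0.54887055
109,combined,0.57961128
110,combined,0.61070238
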