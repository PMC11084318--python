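# kvp: 100
# label: w_al_100kvp
energy_keV	relative_fluence
5	6.30341e-119
5.5	7.59575e-91
6	4.03576e-71
6.5	7.53257e-57
7	2.89892e-46
7.5	3.03902e-38
8	4.70808e-32
8.5	4.12674e-27
9	3.42289e-23
9.5	4.79894e-20
10	1.72518e-17
10.5	2.23165e-15
11	1.24594e-13
11.5	3.56996e-12
12	5.99053e-11
12.5	6.51841e-10
13	4.97956e-09
13.5	2.8431e-08
14	1.27511e-07
14.5	4.67504e-07
15	1.44711e-06
15.5	3.84453e-06
16	9.06322e-06
16.5	1.92912e-05
17	3.76125e-05
17.5	6.79884e-05
18	0.000115096
18.5	0.000184042
19	0.000279992
19.5	0.000407782
20	0.000571547
20.5	0.000760596
21	0.000985076
21.5	0.00124534
22	0.00154075
22.5	0.00186975
23	0.00223001
23.5	0.00261851
24	0.00303176
24.5	0.00346593
25	0.00391699
25.5	0.00438082
26	0.00485336
26.5	0.0053307
27	0.00580911
27.5	0.00628515
28	0.00675564
28.5	0.00721775
29	0.00766897
29.5	0.00810712
30	0.00853034
30.5	0.00885488
31	0.00916353
31.5	0.00945589
32	0.00973165
32.5	0.00999068
33	0.0102329
33.5	0.0104585
34	0.0106675
34.5	0.0108601
35	0.0110368
35.5	0.0111977
36	0.0113433
36.5	0.0114741
37	0.0115905
37.5	0.0116929
38	0.0117819
38.5	0.0118579
39	0.0119215
39.5	0.0119732
40	0.0120134
40.5	0.0119925
41	0.0119645
41.5	0.0119297
42	0.0118885
42.5	0.0118413
43	0.0117884
43.5	0.01173
44	0.0116666
44.5	0.0115985
45	0.0115258
45.5	0.0114489
46	0.0113681
46.5	0.0112835
47	0.0111955
47.5	0.0111042
48	0.0110099
48.5	0.0109128
49	0.010813
49.5	0.0107108
50	0.0106063
50.5	0.0104784
51	0.0103499
51.5	0.010221
52	0.0100918
52.5	0.00996223
53	0.00983248
53.5	0.00970259
54	0.00957261
54.5	0.00944261
55	0.00931265
55.5	0.00918277
56	0.00905303
56.5	0.00892347
57	0.00879413
57.5	0.00866506
58	0.0085363
58.5	0.00840787
59	0.00827982
59.5	0.00815217
60	0.00802496
60.5	0.00788729
61	0.00775079
61.5	0.00761545
62	0.00748127
62.5	0.00734824
63	0.00721636
63.5	0.0070856
64	0.00695597
64.5	0.00682745
65	0.00670005
65.5	0.00657374
66	0.00644853
66.5	0.00632439
67	0.00620133
67.5	0.00607934
68	0.00595839
68.5	0.00583849
69	0.00571963
69.5	0.0056018
70	0.00548498
70.5	0.00536917
71	0.00525435
71.5	0.00514053
72	0.00502768
72.5	0.00491581
73	0.00480489
73.5	0.00469492
74	0.0045859
74.5	0.00447781
75	0.00437064
75.5	0.00426438
76	0.00415902
76.5	0.00405456
77	0.00395099
77.5	0.00384829
78	0.00374646
78.5	0.00364549
79	0.00354537
79.5	0.00344608
80	0.00334763
80.5	0.00324799
81	0.00314932
81.5	0.00305161
82	0.00295484
82.5	0.002859
83	0.00276407
83.5	0.00267004
84	0.0025769
84.5	0.00248464
85	0.00239324
85.5	0.0023027
86	0.00221299
86.5	0.00212411
87	0.00203605
87.5	0.00194879
88	0.00186233
88.5	0.00177665
89	0.00169175
89.5	0.00160761
90	0.00152421
90.5	0.00144157
91	0.00135965
91.5	0.00127845
92	0.00119797
92.5	0.00111819
93	0.00103911
93.5	0.000960711
94	0.000882988
94.5	0.000805932
95	0.000729535
95.5	0.000653788
96	0.000578683
96.5	0.000504212
97	0.000430367
97.5	0.000357139
98	0.000284522
98.5	0.000212506
99	0.000141086
99.5	7.02528e-05
100	0
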