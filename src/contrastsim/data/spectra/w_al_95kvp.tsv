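# kvp: 95
# label: w_al_95kvp
energy_keV	relative_fluence
5	4.78018e-58
5.5	1.49517e-44
6	4.4611e-35
6.5	3.16277e-28
7	3.78213e-23
7.5	2.64162e-19
8	2.43143e-16
8.5	5.62681e-14
9	4.19274e-12
9.5	1.32974e-10
10	2.19342e-09
10.5	2.21482e-08
11	1.49413e-07
11.5	7.31869e-07
12	2.77355e-06
12.5	8.54003e-06
13	2.21962e-05
13.5	5.01823e-05
14	0.000101077
14.5	0.000184883
15	0.000311897
15.5	0.000489115
16	0.000724522
16.5	0.00102222
17	0.00138323
17.5	0.00180552
18	0.00228443
18.5	0.00281314
19	0.00338336
19.5	0.00398592
20	0.00461133
20.5	0.00520491
21	0.00580027
21.5	0.00639066
22	0.00697014
22.5	0.00753359
23	0.00807675
23.5	0.00859616
24	0.00908914
24.5	0.00955368
25	0.00998839
25.5	0.0103924
26	0.0107655
26.5	0.0111074
27	0.0114187
27.5	0.0116999
28	0.0119518
28.5	0.0121755
29	0.0123719
29.5	0.0125423
30	0.0126879
30.5	0.0127532
31	0.0128011
31.5	0.0128329
32	0.0128495
32.5	0.0128519
33	0.0128412
33.5	0.0128182
34	0.0127837
34.5	0.0127388
35	0.012684
35.5	0.0126203
36	0.0125483
36.5	0.0124686
37	0.0123819
37.5	0.0122888
38	0.0121898
38.5	0.0120855
39	0.0119763
39.5	0.0118627
40	0.0117451
40.5	0.0116005
41	0.0114548
41.5	0.011308
42	0.0111605
42.5	0.0110123
43	0.0108637
43.5	0.0107148
44	0.0105657
44.5	0.0104165
45	0.0102675
45.5	0.0101186
46	0.00996999
46.5	0.00982176
47	0.00967399
47.5	0.00952675
48	0.00938011
48.5	0.00923414
49	0.00908889
49.5	0.00894442
50	0.00880078
50.5	0.00864951
51	0.0084998
51.5	0.00835165
52	0.00820504
52.5	0.00805999
53	0.00791646
53.5	0.00777447
54	0.007634
54.5	0.00749504
55	0.00735757
55.5	0.00722159
56	0.00708709
56.5	0.00695405
57	0.00682246
57.5	0.0066923
58	0.00656357
58.5	0.00643624
59	0.00631031
59.5	0.00618576
60	0.00606257
60.5	0.00593678
61	0.0058126
61.5	0.00569001
62	0.00556897
62.5	0.00544946
63	0.00533145
63.5	0.00521491
64	0.00509982
64.5	0.00498615
65	0.00487388
65.5	0.00476298
66	0.00465344
66.5	0.00454522
67	0.0044383
67.5	0.00433266
68	0.00422828
68.5	0.00412514
69	0.00402321
69.5	0.00392248
70	0.00382292
70.5	0.00372453
71	0.00362726
71.5	0.00353112
72	0.00343608
72.5	0.00334211
73	0.00324921
73.5	0.00315736
74	0.00306654
74.5	0.00297673
75	0.00288791
75.5	0.00280008
76	0.00271321
76.5	0.00262729
77	0.00254231
77.5	0.00245824
78	0.00237508
78.5	0.00229281
79	0.00221142
79.5	0.0021309
80	0.00205122
80.5	0.0019718
81	0.00189325
81.5	0.00181557
82	0.00173875
82.5	0.00166276
83	0.0015876
83.5	0.00151325
84	0.0014397
84.5	0.00136693
85	0.00129494
85.5	0.0012237
86	0.00115321
86.5	0.00108346
87	0.00101444
87.5	0.000946123
88	0.000878512
88.5	0.000811593
89	0.000745354
89.5	0.000679786
90	0.000614878
90.5	0.00055062
91	0.000487003
91.5	0.000424016
92	0.00036165
92.5	0.000299897
93	0.000238746
93.5	0.00017819
94	0.000118219
94.5	5.88252e-05
95	0
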