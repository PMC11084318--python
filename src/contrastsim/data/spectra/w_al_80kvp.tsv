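# kvp: 80
# label: w_al_80kvp
energy_keV	relative_fluence
5	6.09249e-58
5.5	1.90351e-44
6	5.67303e-35
6.5	4.01739e-28
7	4.79853e-23
7.5	3.34759e-19
8	3.07757e-16
8.5	7.11352e-14
9	5.29406e-12
9.5	1.67696e-10
10	2.76269e-09
10.5	2.78611e-08
11	1.87711e-07
11.5	9.18267e-07
12	3.47535e-06
12.5	1.06866e-05
13	2.77378e-05
13.5	6.26248e-05
14	0.000125963
14.5	0.000230078
15	0.000387584
15.5	0.000606926
16	0.00089771
16.5	0.00126468
17	0.00170872
17.5	0.00222697
18	0.00281326
18.5	0.00345889
19	0.00415332
19.5	0.00488504
20	0.0056422
20.5	0.00635778
21	0.00707294
21.5	0.0077794
22	0.00846991
22.5	0.00913827
23	0.00977937
23.5	0.0103891
24	0.0109644
24.5	0.0115029
25	0.0120031
25.5	0.0124641
26	0.0128857
26.5	0.0132681
27	0.0136118
27.5	0.0139178
28	0.0141872
28.5	0.0144212
29	0.0146216
29.5	0.0147897
30	0.0149272
30.5	0.0149691
31	0.0149898
31.5	0.0149908
32	0.0149734
32.5	0.0149388
33	0.0148882
33.5	0.014823
34	0.0147441
34.5	0.0146526
35	0.0145496
35.5	0.0144359
36	0.0143125
36.5	0.0141802
37	0.0140397
37.5	0.0138919
38	0.0137373
38.5	0.0135767
39	0.0134106
39.5	0.0132396
40	0.0130643
40.5	0.0128591
41	0.0126529
41.5	0.0124459
42	0.0122383
42.5	0.0120305
43	0.0118225
43.5	0.0116145
44	0.0114067
44.5	0.0111993
45	0.0109924
45.5	0.0107861
46	0.0105806
46.5	0.0103759
47	0.0101721
47.5	0.00996933
48	0.00976769
48.5	0.00956722
49	0.00936799
49.5	0.00917007
50	0.0089735
50.5	0.00876971
51	0.00856813
51.5	0.00836873
52	0.00817151
52.5	0.00797645
53	0.00778355
53.5	0.00759277
54	0.00740412
54.5	0.00721756
55	0.00703309
55.5	0.00685068
56	0.00667031
56.5	0.00649197
57	0.00631563
57.5	0.00614128
58	0.00596888
58.5	0.00579842
59	0.00562988
59.5	0.00546324
60	0.00529847
60.5	0.00513214
61	0.00496795
61.5	0.00480586
62	0.00464585
62.5	0.00448786
63	0.00433187
63.5	0.00417784
64	0.00402573
64.5	0.00387551
65	0.00372715
65.5	0.00358061
66	0.00343586
66.5	0.00329287
67	0.00315162
67.5	0.00301206
68	0.00287417
68.5	0.00273793
69	0.0026033
69.5	0.00247025
70	0.00233877
70.5	0.00220882
71	0.00208038
71.5	0.00195342
72	0.00182792
72.5	0.00170385
73	0.00158119
73.5	0.00145993
74	0.00134002
74.5	0.00122146
75	0.00110422
75.5	0.00098828
76	0.000873618
76.5	0.000760214
77	0.00064805
77.5	0.000537104
78	0.000427357
78.5	0.000318792
79	0.00021139
79.5	0.000105131
80	0
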