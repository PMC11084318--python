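# kvp: 46
# label: w_al_46kvp
energy_keV	relative_fluence
5	1.87239e-57
5.5	5.81747e-44
6	1.72394e-34
6.5	1.21376e-27
7	1.44122e-22
7.5	9.9939e-19
8	9.13142e-16
8.5	2.09744e-13
9	1.551e-11
9.5	4.88098e-10
10	7.9876e-09
10.5	8.00058e-08
11	5.3529e-07
11.5	2.60002e-06
12	9.76897e-06
12.5	2.98168e-05
13	7.68052e-05
13.5	0.000172063
14	0.000343342
14.5	0.000622048
15	0.00103919
15.5	0.00161345
16	0.00236569
16.5	0.00330301
17	0.0044219
17.5	0.00570897
18	0.0071426
18.5	0.00869508
19	0.010335
19.5	0.0120293
20	0.0137452
20.5	0.0153182
21	0.0168488
21.5	0.0183162
22	0.0197034
22.5	0.0209963
23	0.0221842
23.5	0.0232591
24	0.0242158
24.5	0.0250514
25	0.0257649
25.5	0.0263572
26	0.0268303
26.5	0.0271875
27	0.0274331
27.5	0.0275717
28	0.0276086
28.5	0.0275495
29	0.0274001
29.5	0.0271663
30	0.0268539
30.5	0.0263513
31	0.0257971
31.5	0.025196
32	0.0245519
32.5	0.023869
33	0.0231509
33.5	0.0224013
34	0.0216233
34.5	0.02082
35	0.0199945
35.5	0.0191493
36	0.018287
36.5	0.0174099
37	0.0165201
37.5	0.0156196
38	0.0147104
38.5	0.0137939
39	0.0128719
39.5	0.0119458
40	0.0110168
40.5	0.010066
41	0.00911956
41.5	0.00817819
42	0.00724234
42.5	0.00631247
43	0.00538899
43.5	0.00447227
44	0.00356262
44.5	0.00266033
45	0.00176565
45.5	0.000878813
46	0
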