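# kvp: 35
# label: rh_rh_35kvp
energy_keV	relative_fluence
5	3.99449e-23
5.5	2.88386e-18
6	9.1252e-15
6.5	3.55116e-12
7	3.24025e-10
7.5	1.0536e-08
8	1.6158e-07
8.5	1.43087e-06
9	8.27549e-06
9.5	3.44972e-05
10	0.000111407
10.5	0.000299635
11	0.00068262
11.5	0.00136053
12	0.00243235
12.5	0.00397755
13	0.00604189
13.5	0.00863045
14	0.0117081
14.5	0.0152056
15	0.0190293
15.5	0.0227188
16	0.0264685
16.5	0.0301883
17	0.0337964
17.5	0.037222
18	0.0404067
18.5	0.0433041
19	0.0458801
19.5	0.0481112
20	0.196922
20.5	0.0512836
21	0.0522408
21.5	0.0528632
22	0.0531627
22.5	0.0898886
23	0.0528531
23.5	0.000807821
24	0.00101366
24.5	0.00124226
25	0.0014896
25.5	0.00174035
26	0.0019967
26.5	0.00225191
27	0.00249869
27.5	0.00272946
28	0.00293656
28.5	0.00311239
29	0.00324963
29.5	0.00334136
30	0.00338117
30.5	0.00336445
31	0.00328476
31.5	0.00313765
32	0.00291945
32.5	0.00262717
33	0.0022586
33.5	0.00181218
34	0.00128703
34.5	0.000682871
35	0
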